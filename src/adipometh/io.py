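"""Readers and writers for the pipeline's on-disk formats.

Everything tabular is tab-separated with a header row and the feature id in
the first column; decimal points are locale-independent.  Gene sets use the
GMT dialect (one set per line: name, description/source, then member
symbols, all tab-separated).  Writers sort nothing silently: row order is
whatever the in-memory object carries, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSet
from .manifest import MANIFEST_COLUMNS
from .synthetic import SimulatedCohort, SyntheticTruth


def _check_unique(index: pd.Index, path, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"{path}: duplicate {what} {dup!r}")


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample numeric TSV (feature ids in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, path, "feature id")
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {df.index[i]!r}, column {col!r}"
            )
        df[col] = numeric
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in matrix")
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="id")


def read_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, group, age, extra covariates)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group", "age"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet missing column {col!r}")
    _check_unique(pd.Index(df["sample_id"]), path, "sample id")
    return df


def write_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV with the standard annotation columns."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    _check_unique(pd.Index(df["probe_id"]), path, "probe id")
    for col in ("gene_symbols", "gene_regions"):
        df[col] = df[col].fillna("").astype(str)
    for col in ("has_common_snp", "snp_within_10bp", "cross_reactive"):
        df[col] = df[col].astype(bool)
    return df[list(MANIFEST_COLUMNS)]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_probeset_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probeset_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"{path}: probeset map missing column {col!r}")
    _check_unique(pd.Index(df["probeset_id"]), path, "probeset id")
    return df


def write_probeset_map(mapping: pd.DataFrame, path) -> None:
    mapping.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, source, members per line)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, source and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, source, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, source=source, members=frozenset(members)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source, *sorted(gs.members)]) + "\n")


def read_external_deltas(path) -> pd.Series:
    """Read an external comparison TSV of probe id + signed delta."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns probe_id and delta")
    _check_unique(pd.Index(df.iloc[:, 0]), path, "probe id")
    return pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(), index=df.iloc[:, 0], name="delta"
    )


def write_external_deltas(deltas: pd.Series, path) -> None:
    pd.DataFrame({"probe_id": deltas.index, "delta": deltas.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cohort bundle


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "dms_delta": truth.dms_delta,
        "de_log2fc": truth.de_log2fc,
        "pair_labels": [
            {"probe_id": p, "gene_symbol": g, "label": lab}
            for (p, g), lab in truth.pair_labels.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        dms_delta={k: float(v) for k, v in payload["dms_delta"].items()},
        de_log2fc={k: float(v) for k, v in payload["de_log2fc"].items()},
        pair_labels={
            (d["probe_id"], d["gene_symbol"]): d["label"]
            for d in payload["pair_labels"]
        },
    )


def write_cohort(cohort: SimulatedCohort, outdir) -> dict[str, Path]:
    """Write a simulated cohort as the standard pipeline input files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": outdir / "betas.tsv",
        "expression": outdir / "expression.tsv",
        "probeset_map": outdir / "probeset_map.tsv",
        "manifest": outdir / "manifest.tsv",
        "sheet": outdir / "samples.tsv",
        "truth": outdir / "truth.json",
    }
    write_matrix(cohort.betas, paths["betas"])
    write_matrix(cohort.expression, paths["expression"])
    write_probeset_map(cohort.probeset_map, paths["probeset_map"])
    write_manifest(cohort.manifest, paths["manifest"])
    write_sheet(cohort.sheet, paths["sheet"])
    write_truth(cohort.truth, paths["truth"])
    return paths
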