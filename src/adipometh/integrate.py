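"""Join differentially methylated sites to differentially expressed genes.

A DMS (differentially methylated site) is joined to a gene when the probe's
manifest entry links it to a gene in the differentially expressed set; the
join is at link level, so one probe can contribute one record per distinct
(gene, region) link.  Each record is classified by direction consistency:
``inverse`` when methylation and expression move in opposite directions in
cases versus controls (the canonical expectation for 5' regulatory regions),
``same`` otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_chisquare

from .diffmeth import DiffMethResult
from .manifest import (
    CPG_CONTEXTS,
    FIVE_PRIME_REGIONS,
    GENE_REGIONS,
    classify_region_counts,
    explode_gene_links,
)

RECORD_COLUMNS = (
    "probe_id",
    "gene_symbol",
    "gene_region",
    "delta_beta",
    "p_adj_meth",
    "fold_change",
    "p_adj_expr",
    "consistency",
)


def consistency_label(delta_beta: float, fold_change: float) -> str:
    """``inverse`` iff methylation and expression change in opposite directions.

    The expression direction is the sign of log(fold_change).  A fold change
    of exactly 1 (no expression change) cannot occur for a gene that passed
    the fold-change gate; on ungated input it is classified ``same`` with a
    warning.
    """
    if fold_change <= 0:
        raise ValueError("fold change must be positive")
    expr_sign = np.sign(np.log(fold_change))
    if expr_sign == 0:
        warnings.warn("fold change exactly 1; classifying as 'same'", stacklevel=2)
        return "same"
    return "inverse" if np.sign(delta_beta) != expr_sign else "same"


def intersect_dms_de(
    dms: list[str],
    manifest: pd.DataFrame,
    meth_result: DiffMethResult,
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """One record per (DMS probe, DE gene, region) link, with consistency.

    ``de_table`` is the called subset from :func:`adipometh.diffexpr.call_de`
    (indexed by gene symbol, with ``fold_change`` and ``p_adj``).  Returns a
    frame with :data:`RECORD_COLUMNS`; the attrs carry ``n_dms`` and
    ``n_genes`` (distinct counts in the intersection).
    """
    dms_set = set(dms)
    links = explode_gene_links(manifest.loc[manifest["probe_id"].isin(dms_set)])
    rows = []
    for row in links.itertuples(index=False):
        if row.gene_symbol not in de_table.index:
            continue
        delta = float(meth_result.table.at[row.probe_id, "delta_beta"])
        fc = float(de_table.at[row.gene_symbol, "fold_change"])
        rows.append(
            {
                "probe_id": row.probe_id,
                "gene_symbol": row.gene_symbol,
                "gene_region": row.gene_region,
                "delta_beta": delta,
                "p_adj_meth": float(meth_result.table.at[row.probe_id, "p_adj"]),
                "fold_change": fc,
                "p_adj_expr": float(de_table.at[row.gene_symbol, "p_adj"]),
                "consistency": consistency_label(delta, fc),
            }
        )
    records = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    records.attrs["n_dms"] = records["probe_id"].nunique()
    records.attrs["n_genes"] = records["gene_symbol"].nunique()
    return records


def direction_table(records: pd.DataFrame) -> tuple[pd.DataFrame, float | None]:
    """Counts of inverse/same records per gene region, plus 5' inverse percent.

    The 5' set is {TSS1500, TSS200, 5UTR, 1stExon}; the percentage is
    inverse / (inverse + same) within that set, rounded to a whole percent.
    On empty input the percentage is None.
    """
    table = pd.DataFrame(0, index=list(GENE_REGIONS), columns=["inverse", "same"])
    if len(records):
        for (region, label), n in (
            records.groupby(["gene_region", "consistency"]).size().items()
        ):
            table.at[region, label] = int(n)
    five = table.loc[list(FIVE_PRIME_REGIONS & set(table.index))].sum()
    total5 = int(five["inverse"] + five["same"])
    pct = round(100.0 * five["inverse"] / total5) if total5 else None
    return table, pct


def dms_genomic_distribution(
    dms: list[str],
    background: list[str],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Observed vs background genomic distribution of a DMS list.

    For each CpG context (per-probe counts, denominators = probes) and each
    gene region (link-level counts, denominators = links), reports the
    proportion among DMS, among the background, their ratio, and a two-sided
    two-proportion chi-square test without continuity correction (Fisher's
    exact test is the caller's recourse for very small counts).  Categories
    absent from the background are skipped with a warning.
    """
    dms_set, bg_set = set(dms), set(background)
    if not dms_set <= bg_set:
        raise ValueError("DMS list must be a subset of the background")
    ctx_dms, reg_dms = classify_region_counts(dms, manifest)
    ctx_bg, reg_bg = classify_region_counts(background, manifest)
    n_dms_probes, n_bg_probes = len(dms_set), len(bg_set)
    n_dms_links, n_bg_links = sum(reg_dms.values()), sum(reg_bg.values())

    rows = []
    specs = [(c, ctx_dms[c], n_dms_probes, ctx_bg[c], n_bg_probes, "cpg_context")
             for c in CPG_CONTEXTS]
    specs += [(r, reg_dms[r], n_dms_links, reg_bg[r], n_bg_links, "gene_region")
              for r in GENE_REGIONS]
    for name, k1, n1, k2, n2, kind in specs:
        if k2 == 0 or n2 == 0:
            warnings.warn(f"category {name!r} absent from background; skipped")
            continue
        p1 = k1 / n1 if n1 else np.nan
        p2 = k2 / n2
        if n1 and 0 < k1 + k2 < n1 + n2:
            _, p, _ = proportions_chisquare([k1, k2], [n1, n2])
        else:
            p = 1.0 if (n1 and k1 / n1 == p2) else np.nan
        rows.append(
            {
                "category": name,
                "kind": kind,
                "n_dms": k1,
                "n_background": k2,
                "prop_dms": p1,
                "prop_background": p2,
                "ratio": p1 / p2 if p2 else np.nan,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def gene_report(
    records: pd.DataFrame,
    meth_result: DiffMethResult,
    expr_table: pd.DataFrame,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene expression summary with per-probe methylation detail rows.

    Mirrors the conventional results-table layout: for each requested gene an
    ``expression`` row (group means, fold change, adjusted p) followed by one
    ``methylation`` row per associated DMS (group mean betas, delta rounded
    to 2 decimals, adjusted p).  Genes without records get the expression row
    only; genes absent from the expression results get an empty placeholder.
    """
    rows = []
    for gene in genes:
        if gene in expr_table.index:
            e = expr_table.loc[gene]
            rows.append(
                {
                    "gene_symbol": gene,
                    "row_type": "expression",
                    "probe_id": "",
                    "gene_region": "",
                    "mean_case": round(float(e["mean_case"]), 2),
                    "mean_control": round(float(e["mean_control"]), 2),
                    "effect": round(float(e["fold_change"]), 2),
                    "p_adj": float(e["p_adj"]),
                }
            )
        else:
            rows.append(
                {
                    "gene_symbol": gene,
                    "row_type": "expression",
                    "probe_id": "",
                    "gene_region": "",
                    "mean_case": np.nan,
                    "mean_control": np.nan,
                    "effect": np.nan,
                    "p_adj": np.nan,
                }
            )
        sub = records.loc[records["gene_symbol"] == gene]
        for rec in sub.sort_values(["gene_region", "probe_id"]).itertuples():
            m = meth_result.table.loc[rec.probe_id]
            rows.append(
                {
                    "gene_symbol": gene,
                    "row_type": "methylation",
                    "probe_id": rec.probe_id,
                    "gene_region": rec.gene_region,
                    "mean_case": round(float(m["mean_beta_case"]), 2),
                    "mean_control": round(float(m["mean_beta_control"]), 2),
                    "effect": round(float(m["mean_beta_case"]) - float(m["mean_beta_control"]), 2),
                    "p_adj": float(m["p_adj"]),
                }
            )
    return pd.DataFrame(rows)
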