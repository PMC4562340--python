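"""Probe annotation model, exclusion filters, and genomic-region classification.

A probe manifest is carried as a :class:`pandas.DataFrame` with one row per
probe and the columns of :data:`MANIFEST_COLUMNS`, mirroring the layout of
Illumina 450K annotation files: gene symbols and gene regions are parallel
semicolon-separated lists, coordinates are 1-based.  Single probes can be
handled as :class:`ProbeAnnotation` records and converted to/from the frame
representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: CpG-density contexts used by the 450K annotation.
CPG_CONTEXTS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Functional gene regions used by the 450K annotation.
GENE_REGIONS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Regions counted as the 5' part of a gene (promoter windows through first exon).
FIVE_PRIME_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

MANIFEST_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "design_type",
    "cpg_context",
    "gene_symbols",
    "gene_regions",
    "has_common_snp",
    "snp_within_10bp",
    "cross_reactive",
)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Annotation of a single array probe.

    ``gene_links`` is a tuple of ``(gene_symbol, gene_region)`` pairs,
    deduplicated while preserving order; an empty tuple marks an intergenic
    probe.  ``has_common_snp`` flags a common SNP (minor allele frequency
    > 10 %) under the probe, ``snp_within_10bp`` a SNP within 10 bp of the
    interrogated CpG, ``cross_reactive`` a probe known to co-hybridise
    elsewhere in the genome.
    """

    probe_id: str
    chromosome: str
    position: int
    design_type: str = "II"
    cpg_context: str = "OpenSea"
    gene_links: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    has_common_snp: bool = False
    snp_within_10bp: bool = False
    cross_reactive: bool = False

    def __post_init__(self) -> None:
        if self.design_type not in ("I", "II"):
            raise ValueError(f"unknown design type {self.design_type!r}")
        if self.cpg_context not in CPG_CONTEXTS:
            raise ValueError(f"unknown CpG context {self.cpg_context!r}")
        seen: list[tuple[str, str]] = []
        for sym, region in self.gene_links:
            if region not in GENE_REGIONS:
                raise ValueError(f"unknown gene region {region!r}")
            if (sym, region) not in seen:
                seen.append((sym, region))
        object.__setattr__(self, "gene_links", tuple(seen))
        if self.position < 1:
            raise ValueError("coordinates are 1-based; position must be >= 1")


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping for sequentially applied probe-exclusion stages.

    Removals are counted against disjoint sets (each probe is charged to the
    first filter that removes it) so that retained + removals = input.
    """

    n_input: int
    n_removed_common_snp: int = 0
    n_removed_proximal_snp: int = 0
    n_removed_detection: int = 0
    n_removed_cross_reactive: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_common_snp
            + self.n_removed_proximal_snp
            + self.n_removed_detection
            + self.n_removed_cross_reactive
        )
        if removed + self.n_retained != self.n_input:
            raise ValueError(
                f"filter report does not balance: {removed} removed + "
                f"{self.n_retained} retained != {self.n_input} input"
            )


def parse_gene_links(symbols: str, regions: str) -> tuple[tuple[str, str], ...]:
    """Parse parallel semicolon-separated symbol/region strings into links."""
    if not symbols or (isinstance(symbols, float) and np.isnan(symbols)):
        return ()
    syms = str(symbols).split(";")
    regs = str(regions).split(";")
    if len(syms) != len(regs):
        raise ValueError(
            f"gene symbol list {symbols!r} and region list {regions!r} "
            "have different lengths"
        )
    seen: list[tuple[str, str]] = []
    for pair in zip(syms, regs):
        if pair not in seen:
            seen.append(pair)
    return tuple(seen)


def probes_to_frame(probes: list[ProbeAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "probe_id": p.probe_id,
            "chromosome": p.chromosome,
            "position": p.position,
            "design_type": p.design_type,
            "cpg_context": p.cpg_context,
            "gene_symbols": ";".join(s for s, _ in p.gene_links),
            "gene_regions": ";".join(r for _, r in p.gene_links),
            "has_common_snp": p.has_common_snp,
            "snp_within_10bp": p.snp_within_10bp,
            "cross_reactive": p.cross_reactive,
        }
        for p in probes
    ]
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def frame_to_probes(manifest: pd.DataFrame) -> list[ProbeAnnotation]:
    out = []
    for row in manifest.itertuples(index=False):
        out.append(
            ProbeAnnotation(
                probe_id=row.probe_id,
                chromosome=str(row.chromosome),
                position=int(row.position),
                design_type=row.design_type,
                cpg_context=row.cpg_context,
                gene_links=parse_gene_links(row.gene_symbols, row.gene_regions),
                has_common_snp=bool(row.has_common_snp),
                snp_within_10bp=bool(row.snp_within_10bp),
                cross_reactive=bool(row.cross_reactive),
            )
        )
    return out


def explode_gene_links(manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per distinct (probe, gene, region) link.

    Intergenic probes contribute no rows.  Links are deduplicated per probe,
    so a probe annotated twice to the same (gene, region) counts once.
    """
    probe_ids: list[str] = []
    genes: list[str] = []
    regions: list[str] = []
    for row in manifest.itertuples(index=False):
        for sym, region in parse_gene_links(row.gene_symbols, row.gene_regions):
            probe_ids.append(row.probe_id)
            genes.append(sym)
            regions.append(region)
    return pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": genes, "gene_region": regions}
    )


def apply_snp_filters(manifest: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop SNP-compromised probes, the common-SNP flag first.

    Probes carrying a common SNP (MAF > 10 %) are removed first; among the
    remainder, probes with any SNP within 10 bp of the interrogated CpG are
    removed.  The retained set equals joint set subtraction; applying the
    stages sequentially only affects how removals are attributed in the
    report.
    """
    n_input = len(manifest)
    common = manifest["has_common_snp"].astype(bool)
    after_common = manifest.loc[~common.to_numpy()]
    proximal = after_common["snp_within_10bp"].astype(bool)
    retained = after_common.loc[~proximal.to_numpy()]
    report = FilterReport(
        n_input=n_input,
        n_removed_common_snp=int(common.sum()),
        n_removed_proximal_snp=int(proximal.sum()),
        n_retained=len(retained),
    )
    return retained.reset_index(drop=True), report


def apply_detection_filter(
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop probes whose worst per-sample detection p exceeds ``threshold``.

    ``detection_p`` is a probe x sample frame indexed by probe id; every
    manifest probe must be present.  This stage is optional and off by
    default in the pipeline: arrays report a detection p per measurement and
    a probe is untrustworthy only if some sample's signal is not above
    background.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"detection threshold must be in (0, 1), got {threshold}")
    missing = manifest.index[~manifest["probe_id"].isin(detection_p.index)]
    if len(missing):
        first = manifest.loc[missing[0], "probe_id"]
        raise KeyError(f"probe {first!r} missing from the detection-p matrix")
    worst = detection_p.loc[manifest["probe_id"]].max(axis=1).to_numpy()
    keep = worst <= threshold
    retained = manifest.loc[keep]
    report = FilterReport(
        n_input=len(manifest),
        n_removed_detection=int((~keep).sum()),
        n_retained=len(retained),
    )
    return retained.reset_index(drop=True), report


def classify_region_counts(
    probe_ids,
    manifest: pd.DataFrame,
    merge_flanks: bool = False,
) -> tuple[dict[str, int], dict[str, int]]:
    """Tally CpG-context and gene-region membership for a probe list.

    CpG contexts are mutually exclusive, so each probe contributes exactly
    one context count.  Gene regions are counted at link level: one count
    per distinct (probe, gene, region) link, so a probe annotated to two
    genes contributes to both regions.  With ``merge_flanks`` the N_/S_
    shores and shelves are reported merged as ``Shore`` and ``Shelf``.
    """
    probe_ids = list(probe_ids)
    sub = manifest.loc[manifest["probe_id"].isin(set(probe_ids))]
    unknown = set(probe_ids) - set(sub["probe_id"])
    if unknown:
        raise KeyError(f"unknown probe id {sorted(unknown)[0]!r}")

    context_counts = {c: 0 for c in CPG_CONTEXTS}
    for ctx, n in sub["cpg_context"].value_counts().items():
        context_counts[ctx] = int(n)
    if merge_flanks:
        merged = {
            "Island": context_counts["Island"],
            "Shore": context_counts["N_Shore"] + context_counts["S_Shore"],
            "Shelf": context_counts["N_Shelf"] + context_counts["S_Shelf"],
            "OpenSea": context_counts["OpenSea"],
        }
        context_counts = merged

    region_counts = {r: 0 for r in GENE_REGIONS}
    links = explode_gene_links(sub)
    if len(links):
        for region, n in links["gene_region"].value_counts().items():
            region_counts[region] = int(n)
    return context_counts, region_counts


def manifest_to_bed(manifest: pd.DataFrame) -> pd.DataFrame:
    """Probe coordinates as BED (0-based half-open) for export."""
    return pd.DataFrame(
        {
            "chrom": manifest["chromosome"].astype(str),
            "start": manifest["position"].astype(int) - 1,
            "end": manifest["position"].astype(int),
            "name": manifest["probe_id"],
        }
    )
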