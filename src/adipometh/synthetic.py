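"""Synthetic methylation + expression cohorts with known planted truth.

The generator emulates a two-group (obese case vs never-obese control)
isolated-fat-cell methylation study with a matched adipose-tissue expression
study, at configurable scale:

* baseline per-probe beta values drawn from a bimodal mixture (a
  low-methylated mode near 0.1 and a high-methylated mode near 0.85), giving
  the strongly dispersed array-wide distribution typical of genome-wide CpG
  panels (mean ~0.42, SD ~0.37 across probes);
* planted differentially methylated sites (DMS) whose group difference in
  beta is drawn from a heavy-tailed law on [0.01, 0.40] with median ~0.09;
* sampling noise added on the M scale (per-probe variances drawn from a
  scaled inverse-chi-square around ``noise_sd_m``), so back-transformed
  betas stay in (0, 1) without truncation;
* a per-probe linear age effect on the M scale, with ages drawn uniformly on
  30-60 years in both groups (age-matched design);
* positive expression signals on a linear scale with planted multiplicative
  group effects; probesets map to genes, a fraction of genes carrying two
  probesets;
* probe annotations (CpG context, design type, gene/region links, SNP and
  cross-reactive flags) drawn at configurable rates;
* direction coupling: for a planted DMS linked to a planted differentially
  expressed gene, the methylation sign is oriented against the expression
  sign with probability ``inverse_prob_5prime`` when the link is in a 5'
  region, and with probability 1/2 elsewhere.

All draws flow from one seeded generator, so an identical config yields
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diffmeth import beta_to_m, m_to_beta
from .manifest import (
    CPG_CONTEXTS,
    FIVE_PRIME_REGIONS,
    GENE_REGIONS,
    MANIFEST_COLUMNS,
)

# Annotation frequencies loosely following the 450K design.
_CONTEXT_WEIGHTS = (0.31, 0.12, 0.10, 0.05, 0.05, 0.37)
_REGION_WEIGHTS = {
    "TSS1500": 0.15,
    "TSS200": 0.10,
    "5UTR": 0.12,
    "1stExon": 0.08,
    "Body": 0.45,
    "3UTR": 0.10,
}
_INTERGENIC_PROB = 0.25
_TWO_LINK_PROB = 0.10
_TYPE_I_PROB = 0.28
_VARIANCE_PRIOR_DF = 20.0  # heterogeneity of per-feature noise variances


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the emulated study: 15 cases vs 14 controls, planted
    delta-beta on [0.01, 0.40] with median ~0.09, ages 30-60 in both groups,
    58 % inverse coupling in 5' regions.  ``age_effect_sd`` is the SD across
    probes of the per-year age slope in M units; ``noise_sd_m`` the typical
    within-group measurement SD in M units; ``noise_sd_log2`` its expression
    counterpart in log2 units.
    """

    n_case: int = 15
    n_control: int = 14
    n_probes: int = 5000
    n_genes: int = 1000
    frac_dms: float = 0.04
    delta_beta_range: tuple[float, float] = (0.01, 0.40)
    frac_de: float = 0.10
    log2fc_range: tuple[float, float] = (0.3, 1.0)
    inverse_prob_5prime: float = 0.58
    age_effect_sd: float = 0.01
    noise_sd_m: float = 0.35
    noise_sd_log2: float = 0.25
    common_snp_rate: float = 0.0
    proximal_snp_rate: float = 0.0
    cross_reactive_rate: float = 0.0
    two_probeset_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.n_probes <= 0 or self.n_genes <= 0:
            raise ValueError("n_probes and n_genes must be positive")
        lo, hi = self.delta_beta_range
        if not 0 < lo <= hi < 1:
            raise ValueError(
                f"delta_beta_range must satisfy 0 < low <= high < 1, got {self.delta_beta_range}"
            )
        lo2, hi2 = self.log2fc_range
        if not 0 < lo2 <= hi2:
            raise ValueError(f"degenerate log2fc_range {self.log2fc_range}")
        for name in (
            "frac_dms",
            "frac_de",
            "inverse_prob_5prime",
            "common_snp_rate",
            "proximal_snp_rate",
            "cross_reactive_rate",
            "two_probeset_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd_m <= 0 or self.noise_sd_log2 <= 0 or self.age_effect_sd < 0:
            raise ValueError("noise SDs must be positive and age_effect_sd >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth planted in a cohort.

    ``dms_delta`` maps probe id -> signed target delta-beta; ``de_log2fc``
    maps gene symbol -> signed log2 fold change; ``pair_labels`` maps
    (probe_id, gene_symbol) -> "inverse"/"same" for every planted DMS linked
    to a planted DE gene, computed by the sign rule from the planted effects.
    """

    dms_delta: dict[str, float] = field(default_factory=dict)
    de_log2fc: dict[str, float] = field(default_factory=dict)
    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    betas: pd.DataFrame  # probes x samples, beta scale
    expression: pd.DataFrame  # probesets x samples, linear scale
    probeset_map: pd.DataFrame  # probeset_id -> gene_symbol
    manifest: pd.DataFrame
    sheet: pd.DataFrame
    truth: SyntheticTruth


def _draw_delta_magnitudes(rng: np.random.Generator, size: int, lo: float, hi: float) -> np.ndarray:
    """Heavy-tailed |delta-beta| on [lo, hi] with median ~ lo + 0.08 * span factor.

    Magnitudes are lo plus an exponential draw, rejected above hi; the
    exponential scale is chosen so the median magnitude sits at
    lo + (0.09 - 0.01) scaled to the configured span, i.e. exactly 0.09 for
    the default (0.01, 0.40) range.
    """
    span = hi - lo
    target_median_excess = 0.08 * span / 0.39
    scale = max(target_median_excess, 1e-9) / np.log(2.0)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = lo + rng.exponential(scale, size=2 * (size - filled) + 8)
        draw = draw[draw <= hi]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _feature_noise_sd(rng: np.random.Generator, size: int, typical_sd: float) -> np.ndarray:
    # scaled inverse-chi-square heterogeneity around typical_sd**2
    chi = rng.chisquare(_VARIANCE_PRIOR_DF, size=size)
    return typical_sd * np.sqrt(_VARIANCE_PRIOR_DF / chi)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one methylation + expression cohort with planted truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control

    # --- sample sheet ------------------------------------------------------
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = ["case"] * config.n_case + ["control"] * config.n_control
    ages = np.round(rng.uniform(30.0, 60.0, size=n), 1)
    sheet = pd.DataFrame({"sample_id": sample_ids, "group": groups, "age": ages})
    case_mask = np.array([g == "case" for g in groups])

    # --- genes and planted expression effects ------------------------------
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    lo2, hi2 = config.log2fc_range
    de_mag = rng.uniform(lo2, hi2, size=n_de)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    de_log2fc = {genes[i]: float(s * m) for i, s, m in zip(de_idx, de_sign, de_mag)}

    # --- probe annotation --------------------------------------------------
    probe_ids = [f"cgS{i + 1:06d}" for i in range(config.n_probes)]
    contexts = rng.choice(CPG_CONTEXTS, size=config.n_probes, p=_CONTEXT_WEIGHTS)
    design = np.where(rng.random(config.n_probes) < _TYPE_I_PROB, "I", "II")
    intergenic = rng.random(config.n_probes) < _INTERGENIC_PROB
    two_link = rng.random(config.n_probes) < _TWO_LINK_PROB
    region_names = list(_REGION_WEIGHTS)
    region_p = np.array([_REGION_WEIGHTS[r] for r in region_names])
    region_p = region_p / region_p.sum()

    gene_links: list[list[tuple[str, str]]] = []
    for i in range(config.n_probes):
        if intergenic[i]:
            gene_links.append([])
            continue
        k = 2 if two_link[i] else 1
        links = []
        for _ in range(k):
            g = genes[int(rng.integers(config.n_genes))]
            r = region_names[int(rng.choice(len(region_names), p=region_p))]
            if (g, r) not in links:
                links.append((g, r))
        gene_links.append(links)

    flags_common = rng.random(config.n_probes) < config.common_snp_rate
    flags_proximal = rng.random(config.n_probes) < config.proximal_snp_rate
    flags_proximal &= ~flags_common  # flagged sets disjoint
    flags_xr = rng.random(config.n_probes) < config.cross_reactive_rate
    positions = np.sort(rng.choice(np.arange(1, 250_000_000), size=config.n_probes, replace=False))
    chroms = rng.integers(1, 23, size=config.n_probes).astype(str)

    # --- planted DMS -------------------------------------------------------
    n_dms = int(round(config.frac_dms * config.n_probes))
    dms_idx = rng.choice(config.n_probes, size=n_dms, replace=False)
    lo, hi = config.delta_beta_range
    magnitudes = _draw_delta_magnitudes(rng, n_dms, lo, hi)

    dms_delta: dict[str, float] = {}
    pair_labels: dict[tuple[str, str], str] = {}
    signed = np.empty(n_dms)
    for j, i in enumerate(dms_idx):
        links = gene_links[i]
        de_link = next(((g, r) for g, r in links if g in de_log2fc), None)
        if de_link is not None:
            # keep exactly one link so the pair label follows the drawn
            # probability, uncorrelated with other links of the same probe
            gene_links[i] = [de_link]
            g, r = de_link
            p_inv = config.inverse_prob_5prime if r in FIVE_PRIME_REGIONS else 0.5
            inverse = rng.random() < p_inv
            expr_sign = np.sign(de_log2fc[g])
            sign = -expr_sign if inverse else expr_sign
            pair_labels[(probe_ids[i], g)] = "inverse" if inverse else "same"
        else:
            sign = rng.choice([-1.0, 1.0])
        signed[j] = sign * magnitudes[j]
        dms_delta[probe_ids[i]] = float(signed[j])

    # --- methylation matrix ------------------------------------------------
    # bimodal baseline: low-methylated and high-methylated modes
    low_mode = rng.random(config.n_probes) < 0.567
    baseline = np.where(
        low_mode,
        rng.beta(2.0, 18.0, size=config.n_probes),
        rng.beta(17.0, 3.0, size=config.n_probes),
    )
    mean_case_beta = baseline.copy()
    mean_ctrl_beta = baseline.copy()
    for j, i in enumerate(dms_idx):
        d = signed[j]
        margin = abs(d) / 2.0 + 0.02
        center = float(np.clip(baseline[i], margin, 1.0 - margin))
        mean_case_beta[i] = center + d / 2.0
        mean_ctrl_beta[i] = center - d / 2.0
    mean_case_beta = np.clip(mean_case_beta, 0.015, 0.985)
    mean_ctrl_beta = np.clip(mean_ctrl_beta, 0.015, 0.985)

    probe_sd = _feature_noise_sd(rng, config.n_probes, config.noise_sd_m)
    age_slope = rng.normal(0.0, config.age_effect_sd, size=config.n_probes)
    m_mean = np.where(
        case_mask[None, :],
        beta_to_m(mean_case_beta)[:, None],
        beta_to_m(mean_ctrl_beta)[:, None],
    )
    m_vals = (
        m_mean
        + age_slope[:, None] * (ages[None, :] - 45.0)
        + rng.normal(0.0, 1.0, size=(config.n_probes, n)) * probe_sd[:, None]
    )
    betas = pd.DataFrame(m_to_beta(m_vals), index=probe_ids, columns=sample_ids)

    # --- expression matrix -------------------------------------------------
    base_log2 = rng.normal(6.6, 1.5, size=config.n_genes)
    gene_sd = _feature_noise_sd(rng, config.n_genes, config.noise_sd_log2)
    lfc = np.array([de_log2fc.get(g, 0.0) for g in genes])
    extra = rng.random(config.n_genes) < config.two_probeset_frac
    ps_ids: list[str] = []
    ps_gene_idx: list[int] = []
    for i in range(config.n_genes):
        n_ps = 2 if extra[i] else 1
        for k in range(n_ps):
            ps_ids.append(f"ps{i + 1:05d}_{k + 1}")
            ps_gene_idx.append(i)
    ps_gene_idx_arr = np.array(ps_gene_idx)
    offsets = rng.normal(0.0, 0.3, size=len(ps_ids))
    log2_mean = (
        base_log2[ps_gene_idx_arr][:, None]
        + offsets[:, None]
        + np.where(case_mask[None, :], 0.5, -0.5) * lfc[ps_gene_idx_arr][:, None]
    )
    noise = rng.normal(0.0, 1.0, size=(len(ps_ids), n)) * gene_sd[ps_gene_idx_arr][:, None]
    expression = pd.DataFrame(
        np.exp2(log2_mean + noise), index=ps_ids, columns=sample_ids
    )
    probeset_map = pd.DataFrame(
        {"probeset_id": ps_ids, "gene_symbol": [genes[i] for i in ps_gene_idx]}
    )

    # --- manifest frame ----------------------------------------------------
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chromosome": chroms,
            "position": positions,
            "design_type": design,
            "cpg_context": contexts,
            "gene_symbols": [";".join(g for g, _ in ls) for ls in gene_links],
            "gene_regions": [";".join(r for _, r in ls) for ls in gene_links],
            "has_common_snp": flags_common,
            "snp_within_10bp": flags_proximal,
            "cross_reactive": flags_xr,
        },
        columns=list(MANIFEST_COLUMNS),
    )

    truth = SyntheticTruth(
        dms_delta=dms_delta, de_log2fc=de_log2fc, pair_labels=pair_labels
    )
    return SimulatedCohort(
        betas=betas,
        expression=expression,
        probeset_map=probeset_map,
        manifest=manifest,
        sheet=sheet,
        truth=truth,
    )


def make_filter_fixture(
    total: int, n_common_snp: int, n_proximal_snp: int, seed: int = 0
) -> pd.DataFrame:
    """Manifest fixture with exact exclusion-flag counts on disjoint probe sets."""
    if total <= 0:
        raise ValueError("total must be positive")
    if n_common_snp < 0 or n_proximal_snp < 0:
        raise ValueError("flag counts must be non-negative")
    if n_common_snp + n_proximal_snp > total:
        raise ValueError(
            f"flag counts {n_common_snp} + {n_proximal_snp} exceed total {total}"
        )
    rng = np.random.default_rng(seed)
    flagged = rng.choice(total, size=n_common_snp + n_proximal_snp, replace=False)
    common = np.zeros(total, dtype=bool)
    proximal = np.zeros(total, dtype=bool)
    common[flagged[:n_common_snp]] = True
    proximal[flagged[n_common_snp:]] = True
    return pd.DataFrame(
        {
            "probe_id": [f"cgF{i + 1:07d}" for i in range(total)],
            "chromosome": "1",
            "position": np.arange(1, total + 1, dtype=np.int64),
            "design_type": "II",
            "cpg_context": "OpenSea",
            "gene_symbols": "",
            "gene_regions": "",
            "has_common_snp": common,
            "snp_within_10bp": proximal,
            "cross_reactive": False,
        },
        columns=list(MANIFEST_COLUMNS),
    )


def make_gene_sets(
    genes,
    n_sets: int,
    set_size: int,
    seed: int = 0,
    enriched_from=None,
    enriched_fraction: float = 0.0,
) -> list:
    """Synthetic gene sets for enrichment testing.

    Each set draws ``set_size`` symbols uniformly from ``genes``; when
    ``enriched_from`` is given, the first set draws ``enriched_fraction`` of
    its members from that pool instead (a constructed enrichment).
    """
    from .enrich import GeneSet

    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets = []
    for s in range(n_sets):
        if s == 0 and enriched_from is not None and enriched_fraction > 0:
            pool = list(enriched_from)
            k = min(int(round(enriched_fraction * set_size)), len(pool))
            members = list(rng.choice(pool, size=k, replace=False))
            rest = [g for g in genes if g not in set(members)]
            members += list(rng.choice(rest, size=set_size - k, replace=False))
        else:
            members = list(rng.choice(genes, size=set_size, replace=False))
        sets.append(GeneSet(name=f"SET{s + 1:03d}", source="synthetic", members=frozenset(members)))
    return sets


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
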