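# Methods

This note documents the statistical model, the defaults and how they were
chosen, the synthetic-data generator's design, numerical details, and the
limits of what the package's tests demonstrate.

## Differential methylation

Beta values are clipped to [ε, 1 − ε] with ε = 1e−6 (below array
quantisation; keeps M values finite) and transformed to M = log2(β/(1−β)).
Inference runs entirely on the M scale; descriptive group summaries are
reported on the beta scale. The reported effect, Δβ, is the difference of
*unadjusted* group mean betas (case − control), while the p-value comes from
the age-adjusted moderated model — the convention that matches how
methylation results tables are printed (group beta means with a
covariate-adjusted p).

Per-probe models are `M ~ 1 + group + covariates` (age by default), fitted
by OLS on all probes at once. The variance prior (d₀, s₀²) is estimated by
moment-matching the log sample variances: with e_g = log s²_g − ψ(d/2) +
log(d/2), solve ψ′(d₀/2) = var(e) − ψ′(d/2) by Newton inversion of the
trigamma function and recover s₀² from the mean equation. When the observed
spread of log-variances does not exceed what a common variance predicts,
d₀ = ∞ and all posterior variances collapse to s₀² (the z-like limit); if
the inversion degenerates, the fit falls back to d₀ = 4 with a warning.
`prior_df=0` bypasses shrinkage entirely (ordinary per-probe t), which the
tests use as an oracle anchor; the implementation is also cross-checked
against Bioconductor limma on a shared fixture (agreement ~1e−14 in t).

Multiple testing uses the Benjamini–Hochberg step-up, implemented directly
(sorted p·m/rank with a reverse cumulative minimum) and cross-checked in
tests against both a definitional O(m²) oracle and statsmodels. The DMS
threshold defaults to **FDR 1 %** — deliberately stringent to suppress
false positives in a genome-scale scan; the expression threshold defaults
to **FDR 5 %** plus the fold-change gate. Both are exposed as parameters.

Global and per-stratum methylation summaries (`global_and_region_means`)
compute a per-sample mean beta over the stratum's probes first and compare
groups with an unpaired t-test on those per-sample means, making the sample
— not the probe — the unit of inference; with ~15 per group this is the
defensible choice, and probe-level testing across hundreds of thousands of
correlated probes would wildly overstate certainty. The pooled-variance t
is the default (Welch available by flag).

## Differential expression

"Highest call" probeset collapsing is interpreted as highest mean signal
across all samples, with ties broken by probeset id; the interpretation is
an operational reading of the usual array convention, and in simulation the
conclusions are insensitive to which probeset of a gene is used. LOC/FLJ
placeholder symbols are dropped before collapsing. The fold-change gate is
symmetric on the log scale: a "20 % change" means ratio ≥ 1.2 or
≤ 1/1.2 ≈ 0.833 (not 0.8); the bound is configurable for users who prefer
the additive reading. Fold changes are displayed as ratios of linear-scale
group means computed before any rounding.

## Integration and direction consistency

DMS are joined to DE genes at the level of manifest links, so one probe
annotated to two genes (or to one gene in two regions) contributes one
record per distinct (gene, region) link. A record is *inverse* when
sign(Δβ) ≠ sign(log fold change). The 5′ set is {TSS1500, TSS200, 5UTR,
1stExon}; the headline percentage is inverse/(inverse+same) within that
set. Genomic-distribution comparisons (DMS vs background) use per-probe
denominators for CpG contexts and per-link denominators for gene regions,
with a two-proportion chi-square test without continuity correction.

## Over-representation

One-sided hypergeometric upper tail, P(X ≥ k) for k hits in an n-gene set
given K hits among N universe genes, BH-adjusted across exactly the sets
tested in a run. The default universe is the set of genes analysed on the
expression platform — web ORA tools often silently use a whole-genome
universe, which inflates expected counts; here the universe is always an
explicit argument. A bundled GMT (`data/lipolysis.gmt`) carries the 18
lipolysis-pathway genes with reported effects; the full 67-gene pathway
list from the literature must be supplied by the user to reproduce
set-level counts, via the same GMT slot.

## Replication

Each discovery DMS found on the replication platform is re-tested with an
unpaired t on M values. Two orientations are implemented:

* `discovery` (default): the one-sided alternative points in the discovery
  direction, so "significant" already implies directional consistency;
* `observed`: the one-sided p is taken in the direction observed in the
  replication cohort and the sign is compared with discovery afterwards —
  the bookkeeping needed when consistent and significant counts are
  reported separately.

A binomial sign test asks whether the consistent fraction among significant
probes exceeds one half. External published DMS lists are consumed as TSVs
of probe id + signed delta; a zero external delta counts as inconsistent
and is logged.

## The synthetic-data generator

The generator emulates the study conditions: 15 cases vs 14 controls
(methylation), an 11 vs 9 subset for expression runs, ages uniform on
30–60 years in both groups (age-matched), planted |Δβ| on [0.01, 0.40]
with median ≈ 0.09.

* **Baseline betas** come from a bimodal mixture — Beta(2, 18) (low mode,
  weight 0.567) and Beta(17, 3) (high mode) — chosen so the across-probe
  mean ≈ 0.42 and SD ≈ 0.37, the strongly dispersed distribution of a
  genome-wide CpG panel.
* **Planted effects**: |Δβ| = 0.01 plus an exponential draw (scale
  0.08/ln 2, rejected above the range top), a heavy-tailed law whose median
  is 0.09 on the default range. The shift is applied symmetrically around
  the baseline on the beta scale, and group means are logit-transformed so
  noise is added on the M scale — betas stay in (0, 1) with no ad-hoc
  truncation.
* **Noise**: per-probe M-scale SDs are drawn as scaled inverse-chi-square
  around `noise_sd_m` = 0.35 with 20 df of heterogeneity. Through the
  delta-method this gives beta-scale SDs of ~0.01 at extreme betas up to
  ~0.09 at mid-range betas, the spread seen in printed per-probe SD
  columns (≈0.02–0.16); the inverse-chi-square form also means the
  moderated-t model is correctly specified, so calibration tests probe the
  estimator rather than model misfit.
* **Age effect**: per-probe slopes N(0, 0.01) M-units/year on top of the
  group effect.
* **Expression**: per-gene log2 baselines N(6.6, 1.5) (linear signals
  centred near a scaling target of ~100), planted log2 fold changes split
  ± half between groups, per-gene log2 noise SD 0.25 with the same 20-df
  heterogeneity. The 0.25 default is calibrated to printed expression
  tables, where per-group SD/mean ratios have median CV ≈ 0.17, i.e.
  log2(1 + CV) ≈ 0.23. About 15 % of genes carry two probesets to exercise
  collapsing.
* **Direction coupling**: when a planted DMS is linked to a planted DE
  gene, its methylation sign opposes the expression sign with probability
  `inverse_prob_5prime` (default 0.58) for 5′-region links and 1/2
  elsewhere. Probes planted as DMS keep exactly one gene link so the label
  law is exactly the configured Bernoulli — multi-link probes would force
  correlated labels across genes. Non-planted probes may carry up to two
  links (~10 %), and ~25 % are intergenic.
* **Determinism**: a single `numpy.random.Generator` seeded from
  `SimulationConfig.seed` drives every draw; identical configs give
  bit-identical cohorts.

What the generator does **not** emulate: probe-type (I/II) intensity bias
(design type is annotated but both types share one noise model — the
pipeline consumes post-normalisation betas by design), spatial correlation
between neighbouring CpGs, batch/chip effects, cell-composition mixtures,
and correlated gene networks. Passing recovery tests therefore demonstrate
the pipeline's correctness under a clean two-group generative model, not
robustness to those artefacts.

## Problem sizes and numerical details

Calibration and recovery checks run at desk scale as the package's own
test conditions: null calibration pools 20 replicate cohorts of 5,000
probes; planted-recall runs use 10 seeds of 5,000 probes (effects ≥ 0.10)
or 1,000 genes; parameter-recovery for the 5′ inverse fraction uses one
20,000-probe cohort with dense coupling (frac_dms 0.2, frac_de 0.5) so the
binomial CI is informative; filter arithmetic runs at the full platform
scale of 485,577 probes. Trigamma inversion uses Newton iteration from
y = 0.5 + 1/x (50 iterations, tolerance 1e−10 relative). Ordering of
called features is by raw p then feature id, making outputs stable under
ties. Degenerate two-sample inputs (zero variance both sides) return p = 1
for equal means and p → 0 with a warning otherwise.

## Known limitations

No surrogate-variable or cell-composition correction; no batch modelling;
no beta-regression alternative to the M-scale linear model; no
IDAT/CEL-level processing (the pipeline consumes normalised betas and
linear expression signals and exposes the pre-normalisation step as the
caller's responsibility). Cross-reactive probes are flagged and reportable
but not removed by default, since a flagged probe can still carry real
signal; the detection-p filter is likewise off by default and opt-in.
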