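"""Differential methylation on M values with empirical-Bayes variance shrinkage.

Beta values (fraction methylated, in (0, 1)) are logit2-transformed to
M values, M = log2(beta / (1 - beta)), which is the homoscedastic scale on
which linear modelling of array methylation is statistically better behaved.
Per-probe linear models (intercept + group + covariates, age by default) are
fitted by ordinary least squares; residual variances are shrunk towards a
prior estimated across probes by moment-matching the distribution of
log sample variances (digamma/trigamma inversion), giving moderated
t-statistics with d0 + d degrees of freedom.  Group-difference summaries are
reported back on the beta scale as delta-beta = mean beta(case) - mean
beta(control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

DEFAULT_EPSILON = 1e-6

GROUP_CASE = "case"
GROUP_CONTROL = "control"


# ---------------------------------------------------------------------------
# beta <-> M transforms


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """log2(beta / (1 - beta)); betas at 0/1 are clipped to [eps, 1 - eps].

    Values outside [0, 1] are rejected; exact 0/1 (below array quantisation)
    are clipped with a warning so the transform stays finite.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("beta values must lie in [0, 1]")
    if np.any(arr < epsilon) or np.any(arr > 1 - epsilon):
        warnings.warn(
            f"beta values at the 0/1 boundary clipped to [{epsilon}, {1 - epsilon}]",
            stacklevel=2,
        )
        arr = np.clip(arr, epsilon, 1 - epsilon)
    out = np.log2(arr / (1.0 - arr))
    return out if out.shape else float(out)


def m_to_beta(m):
    """Inverse logit2: beta = 2**m / (1 + 2**m), numerically stable for any m."""
    arr = np.asarray(m, dtype=float)
    out = special.expit(arr * np.log(2.0))
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(1..m) are
    the sorted raw p-values; ties and the original order are preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# two-sample t


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def _resolve_alternative(sided: str) -> str:
    aliases = {
        "two": "two-sided",
        "two-sided": "two-sided",
        "greater": "greater",
        "less": "less",
    }
    if sided not in aliases:
        raise ValueError(f"sided must be one of {sorted(aliases)}, got {sided!r}")
    return aliases[sided]


def two_sample_t(
    x,
    y,
    variant: str = "pooled",
    sided: str = "two",
) -> TTestResult:
    """Unpaired t-test of mean(x) - mean(y).

    ``variant`` selects the pooled-variance statistic (default) or Welch's
    unequal-variance form.  One-sided alternatives are ``"greater"``
    (mean(x) > mean(y)) and ``"less"``.  Degenerate inputs with zero variance
    on both sides return p = 1 for equal means and p = 0 (with a warning) for
    unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    alternative = _resolve_alternative(sided)
    if np.var(x) == 0 and np.var(y) == 0:
        df = float(x.size + y.size - 2)
        if np.mean(x) == np.mean(y):
            return TTestResult(0.0, df, 1.0)
        warnings.warn(
            "zero variance on both sides with unequal means; p -> 0", stacklevel=2
        )
        t = np.inf if np.mean(x) > np.mean(y) else -np.inf
        p = {"two-sided": 0.0, "greater": float(t < 0), "less": float(t > 0)}[
            alternative
        ]
        return TTestResult(t, df, p)
    res = stats.ttest_ind(
        x, y, equal_var=(variant == "pooled"), alternative=alternative
    )
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def two_sample_t_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
    sided: str = "two",
) -> TTestResult:
    """Unpaired t-test from group summary statistics (mean, SD, n)."""
    alternative = _resolve_alternative(sided)
    res = stats.ttest_ind_from_stats(
        mean1,
        sd1,
        n1,
        mean2,
        sd2,
        n2,
        equal_var=(variant == "pooled"),
        alternative=alternative,
    )
    if variant == "pooled":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TTestResult(float(res.statistic), df, float(res.pvalue))


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    # Newton iteration on trigamma(y) = x, monotone decreasing on (0, inf).
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Under the hierarchical model s2 | sigma2 ~ sigma2 * chi2_df / df with
    sigma2 ~ s0_sq * d0 / chi2_d0, the statistic e = log(s2) - digamma(df/2)
    + log(df/2) has mean log(s0_sq) - digamma(d0/2) + log(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2).  Solving the variance equation by
    trigamma inversion yields the prior degrees of freedom d0; the mean
    equation then yields the prior variance s0_sq.  Returns
    ``(inf, exp(mean(e)))`` when the observed spread of log-variances is no
    larger than expected under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need at least 2 positive sample variances")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = float(_trigamma_inverse(np.array([e_var]))[0])
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    if not np.isfinite(d0) or d0 <= 0:
        warnings.warn("variance-prior estimation failed; falling back to d0=4")
        d0 = 4.0
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


@dataclass
class ModeratedFit:
    """Shared output of the moderated linear-model engine.

    ``table`` has one row per feature: ``coef`` (group effect, case minus
    control on the modelling scale), ``t_mod``, ``p_raw``, ``p_adj`` (BH),
    ``s2`` (residual variance).  ``d0``/``s0_sq`` are the variance-prior
    degrees of freedom and location; ``df_resid`` the residual df; ``df_total
    = d0 + df_resid`` the df of the moderated t.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_resid: float

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def _design_matrix(
    sheet: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    groups = sheet["group"].astype(str)
    bad = set(groups) - {GROUP_CASE, GROUP_CONTROL}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    indicator = (groups == GROUP_CASE).to_numpy(dtype=float)
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    cols = [np.ones(len(sheet)), indicator]
    for cov in covariates:
        if cov not in sheet.columns:
            raise KeyError(f"covariate {cov!r} not in sample sheet")
        vals = sheet[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        cols.append(vals)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, indicator


def moderated_lm(
    Y: np.ndarray,
    X: np.ndarray,
    coef_index: int = 1,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, float]:
    """Row-wise OLS with empirical-Bayes shrinkage of residual variances.

    Returns ``(coef, t_mod, p_raw, d0, s0_sq, df_resid)`` for the coefficient
    at ``coef_index``.  ``prior_df``/``prior_var`` override the estimated
    prior: ``prior_df=0`` reduces to ordinary per-feature t-statistics and
    ``prior_df=inf`` to the fixed-variance (z-like) limit at ``prior_var``.
    """
    n, p = X.shape
    df_resid = n - p
    if df_resid < 3:
        raise ValueError(f"only {df_resid} residual df; need at least 3")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv  # features x p
    resid = Y - B @ X.T
    s2 = np.einsum("ij,ij->i", resid, resid) / df_resid
    v = xtx_inv[coef_index, coef_index]

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        if d0 == 0:
            s0_sq = 0.0
        elif prior_var is not None:
            s0_sq = float(prior_var)
        else:
            _, s0_sq = estimate_variance_prior(s2, df_resid)

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    coef = B[:, coef_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef / np.sqrt(post_var * v)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return coef, t_mod, p_raw, d0, s0_sq, float(df_resid)


@dataclass
class DiffMethResult:
    """Per-probe moderated-test results on the M scale with beta summaries.

    ``table`` is indexed by probe id with columns ``coef_group`` (M units,
    case - control), ``t_mod``, ``p_raw``, ``p_adj``, ``mean_beta_case``,
    ``mean_beta_control``, ``delta_beta``.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_resid: float

    @property
    def df_total(self) -> float:
        return self.d0 + self.df_resid


def fit_moderated(
    matrix_m: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = ("age",),
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DiffMethResult:
    """Moderated group comparison per probe, adjusting for covariates.

    ``matrix_m`` is probes x samples on the M scale; columns must match the
    sample sheet's ``sample_id``.  Group means of beta are computed from the
    back-transformed matrix; ``delta_beta`` is the difference of unadjusted
    group mean betas (case - control), while inference runs on the M scale
    with the covariates in the design.
    """
    sheet = sheet.set_index("sample_id").loc[list(matrix_m.columns)].reset_index()
    X, indicator = _design_matrix(sheet, covariates)
    Y = matrix_m.to_numpy(dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("M-value matrix contains non-finite values")
    coef, t_mod, p_raw, d0, s0_sq, df_resid = moderated_lm(
        Y, X, prior_df=prior_df, prior_var=prior_var
    )
    betas = m_to_beta(Y)
    case = indicator.astype(bool)
    mean_case = betas[:, case].mean(axis=1)
    mean_control = betas[:, ~case].mean(axis=1)
    table = pd.DataFrame(
        {
            "coef_group": coef,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "mean_beta_case": mean_case,
            "mean_beta_control": mean_control,
            "delta_beta": mean_case - mean_control,
        },
        index=matrix_m.index,
    )
    return DiffMethResult(table=table, d0=d0, s0_sq=s0_sq, df_resid=df_resid)


def call_dms(result: DiffMethResult, fdr: float = 0.01) -> list[str]:
    """Probe ids significant at the given BH FDR, ordered by p then id."""
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    hits = result.table.loc[result.table["p_adj"] < fdr]
    order = sorted(hits.index, key=lambda pid: (hits.at[pid, "p_raw"], pid))
    return order


def global_and_region_means(
    matrix_beta: pd.DataFrame,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Group beta averages overall and stratified by CpG context / gene region.

    For each stratum a per-sample mean beta over the stratum's probes is
    computed first, and the two groups are compared with an unpaired t-test
    on those per-sample means, so that the sample (not the probe) is the unit
    of inference.  Strata with no probes are reported with missing values.
    Returns a frame indexed by stratum with columns ``n_probes``,
    ``mean_case``, ``mean_control``, ``diff``, ``abs_diff``, ``t``, ``p``.
    """
    from .manifest import CPG_CONTEXTS, GENE_REGIONS, explode_gene_links

    sheet = sheet.set_index("sample_id").loc[list(matrix_beta.columns)].reset_index()
    case_ids = sheet.loc[sheet["group"] == GROUP_CASE, "sample_id"]
    ctrl_ids = sheet.loc[sheet["group"] == GROUP_CONTROL, "sample_id"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    man = manifest.set_index("probe_id")
    links = explode_gene_links(manifest)

    strata: dict[str, pd.Index] = {"global": matrix_beta.index}
    for ctx in CPG_CONTEXTS:
        ids = man.index[man["cpg_context"] == ctx]
        strata[ctx] = matrix_beta.index.intersection(ids)
    for region in GENE_REGIONS:
        ids = links.loc[links["gene_region"] == region, "probe_id"].unique()
        strata[region] = matrix_beta.index.intersection(ids)

    rows = []
    for name, ids in strata.items():
        if len(ids) == 0:
            rows.append(
                {"stratum": name, "n_probes": 0, "mean_case": np.nan,
                 "mean_control": np.nan, "diff": np.nan, "abs_diff": np.nan,
                 "t": np.nan, "p": np.nan}
            )
            continue
        per_sample = matrix_beta.loc[ids].mean(axis=0)
        x = per_sample[case_ids].to_numpy()
        y = per_sample[ctrl_ids].to_numpy()
        res = two_sample_t(x, y, variant=variant)
        diff = float(x.mean() - y.mean())
        rows.append(
            {
                "stratum": name,
                "n_probes": int(len(ids)),
                "mean_case": float(x.mean()),
                "mean_control": float(y.mean()),
                "diff": diff,
                "abs_diff": abs(diff),
                "t": res.t,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")
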