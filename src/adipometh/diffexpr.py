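"""Differential expression with FDR + fold-change gates and probeset collapsing.

Expression arrives as a probeset x sample matrix of positive, normalised
linear-scale signals (all-probeset scaling to a common target).  Probesets are
collapsed to genes by keeping, per gene, the probeset with the highest mean
signal across all samples ("highest call").  Group comparison reuses the
moderated linear-model engine on log2 signals (no covariates); fold changes
are reported as ratios of linear-scale group means, matching how array
results tables are conventionally printed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffmeth import _design_matrix, bh_adjust, moderated_lm

#: Uncharacterised-transcript placeholder symbols (LOC###### / FLJ#####).
_PLACEHOLDER = re.compile(r"^(LOC\d+|FLJ\d+)$", re.IGNORECASE)


def drop_placeholder_symbols(mapping: pd.DataFrame) -> pd.DataFrame:
    """Remove probesets mapped to LOC/FLJ placeholder symbols.

    ``mapping`` has columns ``probeset_id`` and ``gene_symbol``.
    """
    keep = ~mapping["gene_symbol"].astype(str).str.match(_PLACEHOLDER)
    return mapping.loc[keep].reset_index(drop=True)


def collapse_probesets(
    matrix: pd.DataFrame, mapping: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a probeset-level matrix to genes by highest mean signal.

    For each gene with several probesets the one with the highest mean signal
    across all samples is kept; ties break deterministically on probeset id.
    Returns the gene-level matrix (indexed by gene symbol) and a Series
    mapping gene -> chosen probeset.
    """
    if mapping.empty:
        raise ValueError("probeset->gene mapping is empty")
    mapping = mapping.loc[mapping["probeset_id"].isin(matrix.index)]
    means = matrix.mean(axis=1)
    chosen: dict[str, str] = {}
    for gene, grp in mapping.groupby("gene_symbol", sort=True):
        best = sorted(
            grp["probeset_id"], key=lambda ps: (-means.at[ps], ps)
        )[0]
        chosen[str(gene)] = best
    chosen_s = pd.Series(chosen, name="chosen_probeset")
    gene_matrix = matrix.loc[chosen_s.to_numpy()]
    gene_matrix.index = pd.Index(chosen_s.index, name="gene_symbol")
    return gene_matrix, chosen_s


@dataclass
class DiffExprResult:
    """Per-gene moderated-test results with linear-scale summaries.

    ``table`` is indexed by gene symbol with columns ``mean_case``,
    ``mean_control`` (linear scale), ``fold_change`` (case / control),
    ``log2_fc`` (model coefficient), ``p_raw``, ``p_adj`` and, when
    collapsing was applied, ``chosen_probeset``.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_resid: float


def fit_de(
    gene_matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    chosen: pd.Series | None = None,
) -> DiffExprResult:
    """Moderated group comparison of log2 expression, per gene."""
    if np.any(gene_matrix.to_numpy() <= 0):
        raise ValueError("expression signals must be strictly positive")
    sheet = sheet.set_index("sample_id").loc[list(gene_matrix.columns)].reset_index()
    X, indicator = _design_matrix(sheet, covariates=())
    Y = np.log2(gene_matrix.to_numpy(dtype=float))
    coef, t_mod, p_raw, d0, s0_sq, df_resid = moderated_lm(Y, X)
    case = indicator.astype(bool)
    linear = gene_matrix.to_numpy(dtype=float)
    mean_case = linear[:, case].mean(axis=1)
    mean_control = linear[:, ~case].mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fold_change": mean_case / mean_control,
            "log2_fc": coef,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        },
        index=gene_matrix.index,
    )
    if chosen is not None:
        table["chosen_probeset"] = chosen.reindex(table.index)
    return DiffExprResult(table=table, d0=d0, s0_sq=s0_sq, df_resid=df_resid)


def call_de(
    result: DiffExprResult,
    fdr: float = 0.05,
    fc_threshold: float = 0.2,
) -> pd.DataFrame:
    """Genes passing both the BH FDR gate and a symmetric fold-change gate.

    A gene is called when p_adj < fdr and its linear fold change is at least
    1 + fc_threshold up, or at most 1 / (1 + fc_threshold) down (the
    log-symmetric reading of a "20 % fold change").  Returns a frame indexed
    by gene with the result columns plus ``direction`` in {"up", "down"}.
    """
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1), got {fdr}")
    if fc_threshold <= 0:
        raise ValueError(f"fc_threshold must be positive, got {fc_threshold}")
    tab = result.table
    upper = 1.0 + fc_threshold
    lower = 1.0 / upper
    passing = (tab["p_adj"] < fdr) & (
        (tab["fold_change"] >= upper) | (tab["fold_change"] <= lower)
    )
    out = tab.loc[passing].copy()
    out["direction"] = np.where(out["fold_change"] > 1.0, "up", "down")
    return out.sort_values(["p_raw"], kind="mergesort")
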