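"""Cross-cohort directional replication of a discovery DMS list.

Probes called differentially methylated in a discovery cohort are re-tested
in an independent replication cohort (possibly on a different array
generation, so only the shared probes are used).  Each shared probe gets a
one-sided unpaired t-test in the replication cohort; by default the
alternative is oriented by the discovery effect sign, so a significant probe
replicates both the existence and the direction of the effect.  An
``observed`` orientation is also provided, in which the one-sided p is taken
in the direction observed in the replication cohort and the sign is compared
with discovery afterwards — the bookkeeping used when "significant" and
"directionally consistent" are reported as separate counts.  A binomial sign
test asks whether the consistent fraction among significant probes exceeds
one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import GROUP_CASE, GROUP_CONTROL, beta_to_m, two_sample_t


@dataclass(frozen=True)
class ReplicationSummary:
    """Counts for a replication run.

    ``n_overlap`` probes assayed in both cohorts; ``n_significant`` with
    one-sided p < alpha in the replication cohort; ``n_consistent``
    significant probes whose effect sign matches discovery; ``sign_test_p``
    one-sided binomial p for consistent/significant against 0.5.
    """

    n_overlap: int
    n_significant: int
    n_consistent: int
    sign_test_p: float

    def __post_init__(self) -> None:
        if not self.n_consistent <= self.n_significant <= self.n_overlap:
            raise ValueError("expected n_consistent <= n_significant <= n_overlap")


def replicate(
    discovery_delta: pd.Series,
    replication_matrix: pd.DataFrame,
    replication_sheet: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "pooled",
    orientation: str = "discovery",
) -> tuple[ReplicationSummary, pd.DataFrame]:
    """Re-test discovery DMS in a replication cohort, probe by probe.

    ``discovery_delta`` maps discovery probe ids to their signed effects
    (delta-beta or M-scale coefficient; only the sign is used).
    ``replication_matrix`` holds beta values; tests run on the M scale with a
    plain unpaired t (no covariate adjustment).  Returns the summary and a
    per-probe table (discovery sign, replication delta-beta, t, one-sided p,
    significant, consistent).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if orientation not in ("discovery", "observed"):
        raise ValueError("orientation must be 'discovery' or 'observed'")
    shared = [p for p in discovery_delta.index if p in replication_matrix.index]
    if not shared:
        raise ValueError("no probe overlap between discovery and replication")
    sheet = (
        replication_sheet.set_index("sample_id")
        .loc[list(replication_matrix.columns)]
        .reset_index()
    )
    case = (sheet["group"] == GROUP_CASE).to_numpy()
    ctrl = (sheet["group"] == GROUP_CONTROL).to_numpy()
    M = beta_to_m(replication_matrix.loc[shared].to_numpy(dtype=float))
    B = replication_matrix.loc[shared].to_numpy(dtype=float)

    rows = []
    for i, probe in enumerate(shared):
        disc_sign = int(np.sign(discovery_delta[probe]))
        x, y = M[i, case], M[i, ctrl]
        obs_delta = float(B[i, case].mean() - B[i, ctrl].mean())
        if orientation == "discovery":
            sided = "greater" if disc_sign >= 0 else "less"
            res = two_sample_t(x, y, variant=variant, sided=sided)
            p_one = res.p
        else:
            res = two_sample_t(x, y, variant=variant, sided="two")
            p_one = res.p / 2.0
        significant = p_one < alpha
        consistent = significant and np.sign(obs_delta) == disc_sign
        rows.append(
            {
                "probe_id": probe,
                "discovery_sign": disc_sign,
                "replication_delta_beta": obs_delta,
                "t": res.t,
                "p_one_sided": p_one,
                "significant": bool(significant),
                "consistent": bool(consistent),
            }
        )
    table = pd.DataFrame(rows).set_index("probe_id")
    n_sig = int(table["significant"].sum())
    n_con = int(table["consistent"].sum())
    if n_sig:
        sign_p = float(
            stats.binomtest(n_con, n_sig, 0.5, alternative="greater").pvalue
        )
    else:
        sign_p = 1.0
    summary = ReplicationSummary(
        n_overlap=len(shared),
        n_significant=n_sig,
        n_consistent=n_con,
        sign_test_p=sign_p,
    )
    return summary, table


def overlap_direction(
    discovery_deltas: pd.Series,
    external_deltas: pd.Series,
) -> tuple[int, int]:
    """Count shared probes and sign agreements with an external DMS list.

    ``external_deltas`` maps probe ids to signed effects from a published
    comparison.  A zero external delta counts as inconsistent and is logged.
    Returns ``(n_overlap, n_same_sign)``.
    """
    shared = discovery_deltas.index.intersection(external_deltas.index)
    if len(shared) == 0:
        warnings.warn("no probe overlap with the external comparison")
        return 0, 0
    disc = np.sign(discovery_deltas[shared].to_numpy(dtype=float))
    ext = np.sign(external_deltas[shared].to_numpy(dtype=float))
    n_zero = int(np.sum(ext == 0))
    if n_zero:
        warnings.warn(f"{n_zero} external deltas are exactly zero; counted as inconsistent")
    same = int(np.sum((disc == ext) & (ext != 0)))
    return int(len(shared)), same
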