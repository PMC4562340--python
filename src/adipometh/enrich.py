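"""Hypergeometric over-representation of a hit-gene list in gene sets.

Given a set of "hit" genes (here: differentially expressed genes carrying at
least one DMS), each gene set is tested for over-representation against a
gene universe with the hypergeometric upper tail:  with N universe genes of
which K are hits, drawing the n set members without replacement, the p-value
is P(X >= k) for k observed hits in the set.  The natural universe for this
pipeline is the set of genes analysed on the expression platform; web tools
often default to a whole-genome universe, which changes expected counts and
p-values, so the universe is always explicit here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a free-text source tag."""

    name: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in self.members)
        )


def normalize_symbols(symbols) -> frozenset[str]:
    return frozenset(str(s).upper() for s in symbols)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` observed hits in a set of size ``n``, with ``K`` hits among ``N``
    universe genes; computed via the stable survival function.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    hit_genes,
    sets: list[GeneSet],
    universe,
) -> pd.DataFrame:
    """Over-representation of ``hit_genes`` in each set, BH-adjusted.

    Sets are intersected with the universe before testing; sets with no
    member in the universe are skipped with a warning.  Returns one row per
    tested set, sorted by p, with columns ``observed``, ``expected``
    (n * K / N), ``set_size`` (members in universe), ``hits_in_universe``,
    ``universe_size``, ``p``, ``p_adj``.
    """
    universe = normalize_symbols(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = normalize_symbols(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    N, K = len(universe), len(hits)
    rows = []
    for gs in sets:
        members = gs.members & universe
        if not members:
            warnings.warn(f"gene set {gs.name!r} has no members in the universe")
            continue
        n = len(members)
        k = len(members & hits)
        rows.append(
            {
                "set_name": gs.name,
                "source": gs.source,
                "observed": k,
                "expected": n * K / N,
                "set_size": n,
                "hits_in_universe": K,
                "universe_size": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return out


def proportion_summary(hit_genes, gene_set: GeneSet) -> str:
    """Human-readable "k of n (pct %)" line for one gene set."""
    hits = normalize_symbols(hit_genes)
    n = len(gene_set.members)
    k = len(gene_set.members & hits)
    return f"{k} of {n} ({round(100.0 * k / n)} %)"
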