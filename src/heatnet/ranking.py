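"""Rank tables and rank-correlation coefficients for centrality comparison.

Nodes are ranked in decreasing order of influence (for heatmap this means
increasing value: most negative first).  Ties are handled by two rules:

``tie_method="id"``
    Tied nodes are ordered by ascending node label; the resulting
    *tentative* ranks (a permutation of 1..N) are used as final ranks.

``tie_method="average"``
    Tied groups share the mean of their tentative ranks (the standard
    mid-rank convention).

Both rules are exposed because worked examples in the influential-node
literature mix them; "id" is the default here since it reproduces the
reference hand calculations exactly.

Two rank-correlation coefficients are provided in their textbook forms:

* Spearman: ``rho = 1 - 6 * sum(d_i^2) / (N (N^2 - 1))`` on final ranks;
* Kendall:  ``tau = (N_C - N_D) / (N_C + N_D)`` counting concordant and
  discordant unordered pairs, pairs tied in either ranking excluded.

Note the Kendall denominator is the number of *untied* pairs — this is
neither tau-a (which divides by all pairs) nor tau-b (which corrects the
denominator for ties symmetrically).  The standard tau-b is available as
:func:`kendall_tau_b` for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
import scipy.stats

from .centrality import CentralityVector
from .graph import sorted_labels

__all__ = [
    "RankTable",
    "CorrelationResult",
    "rank_nodes",
    "spearman",
    "kendall",
    "kendall_tau_b",
    "topk",
    "topk_overlap",
    "concordance_table",
]


@dataclass(frozen=True)
class RankTable:
    """Node ranks under one centrality measure and one tie rule."""

    measure: str
    tentative: Mapping[object, int]
    final: Mapping[object, float]
    tie_method: str

    @property
    def nodes(self) -> list:
        return sorted_labels(self.tentative)

    def by_rank(self) -> list:
        """Nodes in rank order (tentative, i.e. id-tie-broken)."""
        return sorted(self.tentative, key=self.tentative.__getitem__)


@dataclass(frozen=True)
class CorrelationResult:
    """Rank-correlation outcome; fields unused by a coefficient are None."""

    rho: float | None = None
    tau: float | None = None
    sum_d_squared: float | None = None
    n_concordant: int | None = None
    n_discordant: int | None = None
    n_excluded_ties: int | None = None


def rank_nodes(cv: CentralityVector, tie_method: str = "id") -> RankTable:
    """Rank nodes by decreasing influence under the given tie rule."""
    if tie_method not in ("id", "average"):
        raise ValueError(f"unknown tie_method {tie_method!r}; use 'id' or 'average'")
    order = sorted_labels(cv.values)
    # stable sort by decreasing influence; label order breaks ties
    ranked = sorted(order, key=cv.influence, reverse=True)
    tentative = {v: i + 1 for i, v in enumerate(ranked)}
    if tie_method == "id":
        final = {v: float(r) for v, r in tentative.items()}
    else:
        final = {}
        for _, group in itertools.groupby(ranked, key=cv.influence):
            group = list(group)
            mean_rank = sum(tentative[v] for v in group) / len(group)
            for v in group:
                final[v] = mean_rank
    return RankTable(cv.measure, tentative, final, tie_method)


def _check_same_nodes(r1: RankTable, r2: RankTable) -> list:
    n1, n2 = set(r1.tentative), set(r2.tentative)
    if n1 != n2:
        raise ValueError("rank tables cover different node sets")
    return sorted_labels(n1)


def spearman(r1: RankTable, r2: RankTable) -> CorrelationResult:
    """Spearman rho on the tables' final ranks, 1 - 6*sum(d^2)/(N(N^2-1))."""
    nodes = _check_same_nodes(r1, r2)
    n = len(nodes)
    if n < 2:
        raise ValueError("Spearman correlation needs at least 2 nodes")
    sum_d2 = sum((r1.final[v] - r2.final[v]) ** 2 for v in nodes)
    rho = 1.0 - 6.0 * sum_d2 / (n * (n * n - 1))
    return CorrelationResult(rho=rho, sum_d_squared=sum_d2)


def kendall(r1: RankTable, r2: RankTable) -> CorrelationResult:
    """Kendall tau = (N_C - N_D)/(N_C + N_D) over unordered node pairs.

    A pair is concordant when both rankings order it the same way,
    discordant when they order it oppositely, and excluded when it is
    tied in either ranking.  Raises when every pair is excluded.
    """
    nodes = _check_same_nodes(r1, r2)
    nc = nd = excluded = 0
    for u, v in itertools.combinations(nodes, 2):
        a = r1.final[u] - r1.final[v]
        b = r2.final[u] - r2.final[v]
        prod = a * b
        if a == 0 or b == 0:
            excluded += 1
        elif prod > 0:
            nc += 1
        else:
            nd += 1
    if nc + nd == 0:
        raise ValueError("Kendall tau undefined: every pair is tied")
    tau = (nc - nd) / (nc + nd)
    return CorrelationResult(
        tau=tau, n_concordant=nc, n_discordant=nd, n_excluded_ties=excluded
    )


def kendall_tau_b(r1: RankTable, r2: RankTable) -> float:
    """Standard tie-corrected Kendall tau-b (for comparison; never default)."""
    nodes = _check_same_nodes(r1, r2)
    x = [r1.final[v] for v in nodes]
    y = [r2.final[v] for v in nodes]
    return float(scipy.stats.kendalltau(x, y, variant="b").statistic)


def concordance_table(r1: RankTable, r2: RankTable) -> pd.DataFrame:
    """Per-node concordant/discordant pair counts, nodes sorted by ``r1`` rank.

    Each unordered pair is attributed to its earlier-ranked node under
    ``r1``, the layout used in hand calculations of Kendall's tau: for a
    node at position i, ``n_concordant`` counts later-ranked nodes whose
    ``r2`` rank is also larger, ``n_discordant`` those whose ``r2`` rank
    is smaller.  Column sums equal N_C and N_D of :func:`kendall`.
    """
    nodes = _check_same_nodes(r1, r2)
    order = sorted(nodes, key=lambda v: (r1.final[v], r1.tentative[v]))
    rows = []
    for i, u in enumerate(order):
        nc = nd = 0
        for v in order[i + 1:]:
            a = r1.final[v] - r1.final[u]
            b = r2.final[v] - r2.final[u]
            if a == 0 or b == 0:
                continue
            if a * b > 0:
                nc += 1
            else:
                nd += 1
        rows.append(
            {
                "node": u,
                f"{r1.measure}_rank": r1.final[u],
                f"{r2.measure}_rank": r2.final[u],
                "n_concordant": nc,
                "n_discordant": nd,
            }
        )
    return pd.DataFrame(rows)


def topk(cv: CentralityVector, k: int) -> list:
    """The k most influential nodes, id-tie-broken, most influential first."""
    n = len(cv.values)
    if not 0 < k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    return rank_nodes(cv, tie_method="id").by_rank()[:k]


def topk_overlap(a: CentralityVector, b: CentralityVector, k: int) -> int:
    """Size of the intersection of two measures' top-k node lists."""
    return len(set(topk(a, k)) & set(topk(b, k)))
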