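"""Barabási–Albert generator, structural summaries, and power-law fits.

The generator grows a network by linear preferential attachment: it
starts from a single node (m0 = 1) and each arriving node connects to
``min(m, existing)`` *distinct* existing nodes, sampled without
replacement with probability proportional to current degree (uniformly
when every candidate still has degree 0, i.e. the very first
attachment).  Under these semantics the edge count is deterministic:

    M = m (N - 1) - m (m - 1) / 2        for N - 1 >= m,

because the i-th arriving node contributes min(m, i - 1) edges.  Mean
degree 2M/N is therefore seed-independent, and m = 1 always yields a
tree (M = N - 1, clustering 0).

The density-to-m design rule is m = round(d N / 2), from d ≈ 2m/N for a
BA graph with m0 = 1.

Degree-distribution scale-freeness is assessed by ordinary least squares
of log P(k) on log k over the degrees present in the graph — a simple
log–log regression, deliberately not a maximum-likelihood tail fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.sparse.csgraph import shortest_path

from .graph import Graph, GraphError, ValidationError

__all__ = [
    "BAConfig",
    "StructuralSummary",
    "PowerLawFit",
    "FitError",
    "generate_ba",
    "m_for_density",
    "clustering_coefficient",
    "diameter",
    "structural_summary",
    "fit_power_law",
]


class FitError(ValueError):
    """Degree distribution has too little support for a power-law fit."""


@dataclass(frozen=True)
class BAConfig:
    """Barabási–Albert generator parameters (m0 fixed at 1)."""

    N: int
    m: int
    m0: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.N < 2:
            raise ValidationError(f"N must be >= 2, got {self.N}")
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if self.m0 != 1:
            raise ValidationError("only m0 = 1 is supported")


@dataclass(frozen=True)
class StructuralSummary:
    """Ensemble mean ± sd of basic structure over generator replicates."""

    mean_degree: tuple[float, float]
    clustering: tuple[float, float]
    diameter: tuple[float, float]
    replicates: int


@dataclass(frozen=True)
class PowerLawFit:
    """Log–log OLS fit of the degree distribution P(k) ~ k^(-gamma)."""

    gamma: float
    r_squared: float
    k_values: np.ndarray
    p_k: np.ndarray


def generate_ba(cfg: BAConfig) -> Graph:
    """Grow one BA network; nodes are labeled 1..N in arrival order.

    Weighted sampling without replacement is performed by sequential
    draws with renormalization over the degrees at the start of the
    arrival (a node's own edges never influence its target choice).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, m = cfg.N, cfg.m
    deg = np.zeros(n, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    for i in range(1, n):  # 0-based index of the arriving node
        k = min(m, i)
        w = deg[:i].astype(float)
        total = w.sum()
        if total == 0:
            targets = rng.choice(i, size=k, replace=False)
        else:
            targets = rng.choice(i, size=k, replace=False, p=w / total)
        for t in targets:
            edges.append((int(t) + 1, i + 1))
        deg[targets] += 1
        deg[i] = k
    return Graph(edges)


def m_for_density(N: int, d: float) -> int:
    """Edges per arrival m = round(d N / 2) hitting a target density."""
    x = d * N / 2.0
    m = int(np.floor(x + 0.5))  # round half away from zero (x >= 0 here)
    if m < 1:
        raise ValidationError(
            f"target density {d} at N={N} implies m={m} < 1; too sparse"
        )
    return m


def _triangle_counts(g: Graph) -> tuple[dict, dict]:
    """Per-node (edges among neighbors, possible neighbor pairs)."""
    adj = g._adj  # internal view: avoids copying neighbor sets in the hot loop
    closed, triples = {}, {}
    for v in g.nodes:
        nbrs = list(adj[v])
        k = len(nbrs)
        triples[v] = k * (k - 1) // 2
        links = 0
        for a, b in itertools.combinations(nbrs, 2):
            if b in adj[a]:
                links += 1
        closed[v] = links
    return closed, triples


def clustering_coefficient(g: Graph, kind: str = "global") -> float:
    """Triangle density of the graph.

    ``kind="global"`` is the transitivity ratio 3·triangles / triples
    (0 when there are no connected triples).  ``kind="mean-local"``
    averages each node's local triangle density, with degree < 2 nodes
    contributing 0.
    """
    if kind not in ("global", "mean-local"):
        raise ValueError(f"unknown clustering kind {kind!r}")
    closed, triples = _triangle_counts(g)
    if kind == "global":
        denom = sum(triples.values())
        return sum(closed.values()) / denom if denom else 0.0
    n = g.n_nodes
    if n == 0:
        return 0.0
    return sum(
        closed[v] / triples[v] for v in g.nodes if triples[v] > 0
    ) / n


def diameter(g: Graph) -> int:
    """Longest shortest path over all node pairs (all-pairs BFS)."""
    if g.n_nodes == 1:
        return 0
    mat, _ = g.adjacency_matrix()
    d = shortest_path(mat, method="D", unweighted=True, directed=False)
    dmax = d.max()
    if np.isinf(dmax):
        raise GraphError("diameter undefined on a disconnected graph")
    return int(round(dmax))


def structural_summary(cfg: BAConfig, replicates: int = 100) -> StructuralSummary:
    """Mean ± sd of mean degree, clustering and diameter over an ensemble.

    Replicate r uses seed ``cfg.rng_seed + r``.  Standard deviations are
    sample (ddof=1) values, 0 for a single replicate.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    mean_deg, clus, diam = [], [], []
    for r in range(replicates):
        g = generate_ba(BAConfig(cfg.N, cfg.m, rng_seed=cfg.rng_seed + r))
        mean_deg.append(2.0 * g.n_edges / g.n_nodes)
        clus.append(clustering_coefficient(g, kind="global"))
        diam.append(diameter(g))

    def _agg(xs: Sequence[float]) -> tuple[float, float]:
        a = np.asarray(xs, dtype=float)
        sd = float(a.std(ddof=1)) if len(a) > 1 else 0.0
        return float(a.mean()), sd

    return StructuralSummary(
        mean_degree=_agg(mean_deg),
        clustering=_agg(clus),
        diameter=_agg(diam),
        replicates=replicates,
    )


def fit_power_law(g: Graph) -> PowerLawFit:
    """OLS of log P(k) on log k; gamma is the negated slope.

    P(k) is the empirical fraction of nodes with degree k; only degrees
    with P(k) > 0 (and k > 0) enter the regression.  Requires at least
    3 distinct positive degrees.
    """
    degrees = np.array([g.degree(v) for v in g.nodes])
    ks, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if len(ks) < 3:
        raise FitError(
            f"need >= 3 distinct positive degrees for a power-law fit, got {len(ks)}"
        )
    pk = counts / g.n_nodes
    res = scipy.stats.linregress(np.log(ks), np.log(pk))
    return PowerLawFit(
        gamma=-float(res.slope),
        r_squared=float(res.rvalue**2),
        k_values=ks,
        p_k=pk,
    )
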