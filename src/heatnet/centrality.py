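"""The five node-centrality measures.

Degree, eigenvector, closeness and betweenness are the four classical
reference measures; the heatmap centrality is the shortest-path measure
this package exists for.  It scores a node by its farness (sum of hop
distances to all other nodes) minus the arithmetic mean of its neighbors'
farness:

    C_HM(v) = F(v) - (1/deg(v)) * sum_{u ~ v} F(u)

A node whose farness is below its neighborhood average sits at a "hot
spot" of the network — shortest paths between other nodes are drawn
through it — so *more negative* heatmap values mean *more* influence.
All other measures follow the usual higher-is-more-influential direction.

Conventions (chosen to be internally consistent and exactly checkable):

* closeness is the unnormalized reciprocal of farness, ``1/F(v)`` — no
  ``(N-1)`` factor;
* betweenness counts each unordered node pair once, endpoints excluded,
  with fractional credit when a pair has several shortest paths;
* eigenvector centrality is the dominant adjacency eigenvector rescaled
  so its maximum entry is exactly 1, computed by power iteration.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .graph import Graph, GraphError, all_farness, is_connected, sorted_labels

__all__ = [
    "CentralityVector",
    "ConvergenceError",
    "MEASURES",
    "degree_centrality",
    "eigenvector_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "heatmap_centrality",
    "all_centralities",
    "centrality_table",
]

#: Canonical measure names, in the order results are reported.
MEASURES = ("degree", "eigenvector", "closeness", "betweenness", "heatmap")


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


@dataclass(frozen=True)
class CentralityVector:
    """Per-node scores for one measure, with its ranking direction.

    ``higher_is_better`` is ``True`` for degree/eigenvector/closeness/
    betweenness and ``False`` for heatmap, where more negative values
    indicate more influential nodes.
    """

    measure: str
    values: Mapping[object, float]
    higher_is_better: bool = True

    def __post_init__(self):
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, node) -> float:
        return self.values[node]

    def influence(self, node) -> float:
        """Score on a scale where larger always means more influential."""
        v = self.values[node]
        return v if self.higher_is_better else -v

    def as_series(self) -> pd.Series:
        order = sorted_labels(self.values)
        return pd.Series([self.values[v] for v in order], index=order,
                         name=self.measure)


def _require_connected(g: Graph, measure: str) -> None:
    if not is_connected(g):
        raise GraphError(f"{measure} centrality requires a connected graph")


def degree_centrality(g: Graph) -> CentralityVector:
    """Number of neighbors of each node."""
    return CentralityVector("degree", {v: g.degree(v) for v in g.nodes})


def eigenvector_centrality(
    g: Graph, tol: float = 1e-12, max_iter: int = 10_000
) -> CentralityVector:
    """Dominant adjacency eigenvector, max-entry normalized to 1.

    Power iteration from the uniform positive vector; on a connected
    graph the Perron–Frobenius eigenvector is strictly positive and the
    iteration converges to it.  The iteration uses the shifted operator
    A + I, which shares A's eigenvectors but makes the Perron eigenvalue
    strictly dominant in magnitude — plain iteration on A never settles
    on bipartite graphs, where -lambda_max ties it.  Convergence is
    declared when the max-norm change of the (max-normalized) iterate
    drops to ``tol``.
    """
    _require_connected(g, "eigenvector")
    mat, order = g.adjacency_matrix()
    n = len(order)
    if n == 1:
        return CentralityVector("eigenvector", {order[0]: 1.0})
    x = np.ones(n)
    for _ in range(max_iter):
        y = mat @ x + x  # (A + I) x
        nrm = y.max()
        if nrm == 0:  # pragma: no cover - impossible on connected N>=2
            raise ConvergenceError("zero iterate in power iteration")
        y /= nrm
        residual = np.abs(y - x).max()
        x = y
        if residual <= tol:
            x = x / x.max()
            return CentralityVector(
                "eigenvector", {v: float(val) for v, val in zip(order, x)}
            )
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(residual {residual:.3e} > tol {tol:.1e})"
    )


def closeness_centrality(g: Graph) -> CentralityVector:
    """Reciprocal farness 1/F(v) (unnormalized)."""
    far = all_farness(g)  # raises GraphError when disconnected
    if g.n_nodes == 1:
        raise GraphError("closeness undefined for a single-node graph")
    return CentralityVector("closeness", {v: 1.0 / f for v, f in far.items()})


def betweenness_centrality(g: Graph) -> CentralityVector:
    """Shortest-path betweenness by Brandes' dependency accumulation.

    Each unordered pair {j, k} with j, k != v contributes
    sigma_jk(v) / sigma_jk, the fraction of j–k shortest paths passing
    through v.  Disconnected graphs are allowed: unreachable pairs
    contribute nothing.
    """
    nodes = g.nodes
    bet = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        # single-source shortest-path counts (augmented BFS)
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            du = dist[u]
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = du + 1
                    queue.append(w)
                if dist[w] == du + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        # dependency accumulation in reverse BFS order
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w] if sigma[w] else 0.0
            for u in pred[w]:
                delta[u] += sigma[u] * coeff
            if w != s:
                bet[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return CentralityVector("betweenness", {v: b / 2.0 for v, b in bet.items()})


def heatmap_centrality(g: Graph) -> CentralityVector:
    """Farness minus mean neighbor farness; more negative = more influential.

    Farness of every node is computed once in a single all-pairs BFS
    sweep and reused for all neighbor averages (O(N(N+M)) total).
    Requires a connected graph with at least 2 nodes (every node then has
    degree >= 1, so the neighbor mean is defined).
    """
    far = all_farness(g)  # raises GraphError when disconnected
    if g.n_nodes < 2:
        raise GraphError("heatmap centrality undefined for a single-node graph")
    values = {}
    for v in g.nodes:
        nbrs = g.neighbors(v)
        values[v] = far[v] - sum(far[u] for u in nbrs) / len(nbrs)
    return CentralityVector("heatmap", values, higher_is_better=False)


def all_centralities(g: Graph) -> dict[str, CentralityVector]:
    """All five measures, sharing one all-pairs BFS for closeness/heatmap."""
    _require_connected(g, "all_centralities")
    far = all_farness(g)
    if g.n_nodes < 2:
        raise GraphError("centrality table requires at least 2 nodes")
    closeness = CentralityVector(
        "closeness", {v: 1.0 / f for v, f in far.items()}
    )
    heat = {}
    for v in g.nodes:
        nbrs = g.neighbors(v)
        heat[v] = far[v] - sum(far[u] for u in nbrs) / len(nbrs)
    return {
        "degree": degree_centrality(g),
        "eigenvector": eigenvector_centrality(g),
        "closeness": closeness,
        "betweenness": betweenness_centrality(g),
        "heatmap": CentralityVector("heatmap", heat, higher_is_better=False),
    }


def centrality_table(
    g: Graph, measures: tuple[str, ...] = MEASURES
) -> pd.DataFrame:
    """Node-by-measure DataFrame of centrality values (with rank columns)."""
    from .ranking import rank_nodes  # local import to avoid a cycle

    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    cvs = all_centralities(g)
    order = g.nodes
    data: dict[str, list] = {"node": order}
    for m in MEASURES:
        if m not in measures:
            continue
        cv = cvs[m]
        rt = rank_nodes(cv, tie_method="id")
        data[m] = [cv[v] for v in order]
        data[f"{m}_rank"] = [rt.tentative[v] for v in order]
    return pd.DataFrame(data)
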