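"""Simple undirected graph container, edge-list I/O and BFS utilities.

The package works exclusively with simple (no loops, no multi-edges),
undirected, unweighted graphs.  Node labels are preserved as given —
integers or strings — and every iteration order is deterministic:
ascending numeric order when all labels are integers, lexicographic
otherwise.  Downstream tie-breaking (rank tables, top-k lists) relies on
this ordering.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Graph",
    "GraphError",
    "ParseError",
    "ValidationError",
    "DistanceMap",
    "PreprocessReport",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "bfs_distances",
    "farness",
    "all_farness",
    "is_connected",
    "connected_components",
    "largest_component",
    "preprocess_real_world",
    "density",
]


class GraphError(ValueError):
    """A graph does not satisfy a structural precondition (e.g. connectivity)."""


class ParseError(ValueError):
    """An input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Input violates a validity rule (loop, duplicate edge, empty input, ...)."""


def _label_key(label):
    """Sort key placing integer labels in numeric order before any strings."""
    if isinstance(label, bool):  # bool is an int subclass; treat as label text
        return (1, str(label))
    if isinstance(label, (int, np.integer)):
        return (0, int(label))
    return (1, str(label))


def sorted_labels(labels: Iterable) -> list:
    """Deterministic node ordering: numeric ascending, then lexicographic."""
    return sorted(labels, key=_label_key)


class Graph:
    """Simple undirected unweighted graph.

    Parameters
    ----------
    edges
        Iterable of 2-tuples of node labels.  Duplicate edges (in either
        orientation) collapse silently; self-loops raise ``ValidationError``.
    nodes
        Optional extra labels to include as (possibly isolated) nodes.
    """

    __slots__ = ("_adj", "_m")

    def __init__(self, edges: Iterable[tuple] = (), nodes: Iterable = ()):
        self._adj: dict[object, set] = {}
        self._m = 0
        for v in nodes:
            self._adj.setdefault(v, set())
        for u, v in edges:
            self.add_edge(u, v)

    def add_edge(self, u, v) -> None:
        if u == v:
            raise ValidationError(f"self-loop on node {u!r} is not allowed")
        a = self._adj.setdefault(u, set())
        b = self._adj.setdefault(v, set())
        if v not in a:
            a.add(v)
            b.add(u)
            self._m += 1

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return self._m

    @property
    def nodes(self) -> list:
        return sorted_labels(self._adj)

    def __contains__(self, v) -> bool:
        return v in self._adj

    def __len__(self) -> int:
        return len(self._adj)

    def neighbors(self, v) -> set:
        try:
            return set(self._adj[v])
        except KeyError:
            raise KeyError(f"node {v!r} not in graph") from None

    def degree(self, v) -> int:
        try:
            return len(self._adj[v])
        except KeyError:
            raise KeyError(f"node {v!r} not in graph") from None

    def edges(self) -> Iterator[tuple]:
        """Each undirected edge once, as a label-ordered pair, sorted."""
        seen = []
        for u in self.nodes:
            for v in self._adj[u]:
                if _label_key(u) < _label_key(v):
                    seen.append((u, v))
        return iter(sorted(seen, key=lambda e: (_label_key(e[0]), _label_key(e[1]))))

    def subgraph(self, keep: Iterable) -> "Graph":
        keep = set(keep)
        missing = keep - self._adj.keys()
        if missing:
            raise KeyError(f"nodes not in graph: {sorted_labels(missing)!r}")
        g = Graph(nodes=keep)
        for u in keep:
            for v in self._adj[u]:
                if v in keep and _label_key(u) < _label_key(v):
                    g.add_edge(u, v)
        return g

    def adjacency_matrix(self) -> tuple[sp.csr_matrix, list]:
        """CSR adjacency matrix and the node list indexing its rows."""
        order = self.nodes
        index = {v: i for i, v in enumerate(order)}
        rows, cols = [], []
        for u in order:
            for v in self._adj[u]:
                rows.append(index[u])
                cols.append(index[v])
        data = np.ones(len(rows))
        mat = sp.csr_matrix((data, (rows, cols)), shape=(len(order), len(order)))
        return mat, order

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Graph(N={self.n_nodes}, M={self.n_edges})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._adj == other._adj

    def __hash__(self):
        return None  # mutable


@dataclass(frozen=True)
class DistanceMap:
    """BFS hop distances from one source node.

    ``dist`` holds finite distances for reachable nodes only; unreachable
    nodes are absent.  ``reached`` counts the source's component size.
    """

    source: object
    dist: Mapping[object, int]
    reached: int


@dataclass(frozen=True)
class PreprocessReport:
    """Outcome of cleaning a raw (possibly directed/multi) edge record set."""

    nodes_removed: int
    edges_removed: int
    made_undirected: bool
    result: Graph


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _convert_labels(raw_edges: list[tuple[str, str]]) -> list[tuple]:
    """Convert all labels to int when every token parses as an integer."""
    tokens = set(itertools.chain.from_iterable(raw_edges))
    try:
        mapping = {t: int(t) for t in tokens}
    except ValueError:
        return raw_edges
    return [(mapping[u], mapping[v]) for u, v in raw_edges]


def read_edge_list(
    path: str | Path,
    delimiter: str | None = None,
    simplify: bool = False,
    comment: str = "#",
) -> Graph:
    """Read a two-column edge list into a :class:`Graph`.

    ``delimiter=None`` splits on any run of whitespace and/or commas.  Lines
    starting with ``comment`` and blank lines are skipped.  When ``simplify``
    is set, self-loops and repeated edges are silently dropped; otherwise
    they raise :class:`ValidationError` with the line number.
    """
    raw: list[tuple[str, str]] = []
    lines: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment):
                continue
            if delimiter is None:
                parts = line.replace(",", " ").split()
            else:
                parts = [p.strip() for p in line.split(delimiter)]
                parts = [p for p in parts if p]
            if len(parts) < 2:
                raise ParseError(
                    f"expected at least two tokens, got {len(parts)}", lineno
                )
            raw.append((parts[0], parts[1]))
            lines.append(lineno)
    edges = _convert_labels(raw)
    g = Graph()
    seen: set[frozenset] = set()
    for (u, v), lineno in zip(edges, lines):
        if u == v:
            if simplify:
                continue
            raise ValidationError(f"line {lineno}: self-loop {u!r}-{v!r}")
        key = frozenset((u, v))
        if key in seen:
            if simplify:
                continue
            raise ValidationError(f"line {lineno}: duplicate edge {u!r}-{v!r}")
        seen.add(key)
        g.add_edge(u, v)
    return g


def write_edge_list(g: Graph, path: str | Path, delimiter: str = " ") -> None:
    with open(path, "w") as fh:
        for u, v in g.edges():
            fh.write(f"{u}{delimiter}{v}\n")


def read_graphml(path: str | Path) -> Graph:
    """Read a GraphML file (via networkx) into a simple undirected graph."""
    import networkx as nx

    gx = nx.read_graphml(path)
    gx = nx.Graph(gx)  # collapse direction / multi-edges
    edges = _convert_labels([(str(u), str(v)) for u, v in gx.edges() if u != v])
    nodes = _convert_labels([(str(v), str(v)) for v in gx.nodes()])
    return Graph(edges, nodes=[n for n, _ in nodes])


def write_graphml(g: Graph, path: str | Path) -> None:
    import networkx as nx

    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    gx.add_edges_from(g.edges())
    nx.write_graphml(gx, path)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def bfs_distances(g: Graph, source) -> DistanceMap:
    """Hop distances from ``source`` by breadth-first search, O(N + M)."""
    if source not in g:
        raise KeyError(f"source node {source!r} not in graph")
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in g._adj[u]:
            if v not in dist:
                dist[v] = du + 1
                queue.append(v)
    return DistanceMap(source=source, dist=dist, reached=len(dist))


def farness(g: Graph, v) -> int:
    """Sum of shortest-path distances from ``v`` to every other node.

    Defined only on connected graphs: an unreachable node would make the
    sum infinite, so disconnected input raises :class:`GraphError`.
    """
    dm = bfs_distances(g, v)
    if dm.reached < g.n_nodes:
        raise GraphError(
            f"farness undefined: {g.n_nodes - dm.reached} nodes unreachable from {v!r}"
        )
    return sum(dm.dist.values())


def all_farness(g: Graph) -> dict:
    """Farness of every node from one all-pairs BFS sweep, O(N(N+M)).

    Uses compiled all-pairs unweighted shortest paths for speed; agrees
    exactly with per-node :func:`farness`.
    """
    if g.n_nodes == 1:
        return {v: 0 for v in g.nodes}
    mat, order = g.adjacency_matrix()
    d = shortest_path(mat, method="D", unweighted=True, directed=False)
    if np.isinf(d).any():
        raise GraphError("farness undefined on a disconnected graph")
    totals = d.sum(axis=1)
    return {v: int(round(t)) for v, t in zip(order, totals)}


# ---------------------------------------------------------------------------
# Connectivity and preprocessing
# ---------------------------------------------------------------------------

def connected_components(g: Graph) -> list[list]:
    """Components as label-sorted node lists, ordered by (-size, min label)."""
    seen: set = set()
    comps: list[list] = []
    for v in g.nodes:
        if v in seen:
            continue
        comp = bfs_distances(g, v).dist.keys()
        seen.update(comp)
        comps.append(sorted_labels(comp))
    comps.sort(key=lambda c: (-len(c), _label_key(c[0])))
    return comps


def is_connected(g: Graph) -> bool:
    if g.n_nodes == 0:
        raise ValidationError("connectivity undefined for the empty graph")
    first = g.nodes[0]
    return bfs_distances(g, first).reached == g.n_nodes


def largest_component(g: Graph) -> Graph:
    """Induced subgraph on the biggest component (ties: smallest node label)."""
    comps = connected_components(g)
    if not comps:
        raise ValidationError("empty graph has no components")
    return g.subgraph(comps[0])


def preprocess_real_world(
    edges: Iterable[tuple],
    nodes: Iterable = (),
) -> PreprocessReport:
    """Clean raw edge records the way real-world network data is prepared.

    Records may be directed, repeated, or loops.  The pipeline is:
    treat every record as undirected, drop loops and multi-edges, then keep
    the largest connected component.  ``edges_removed`` counts input records
    that do not survive as edges of the result; ``nodes_removed`` counts
    labels (including explicitly passed isolated nodes) outside the result.
    """
    records = list(edges)
    extra_nodes = list(nodes)
    if not records and not extra_nodes:
        raise ValidationError("no edge records or nodes supplied")

    all_labels: set = set(extra_nodes)
    undirected: set[frozenset] = set()
    ordered_seen: set[tuple] = set()
    made_undirected = False
    for u, v in records:
        all_labels.update((u, v))
        ordered_seen.add((u, v))
        if u != v:
            if (v, u) in ordered_seen:
                made_undirected = True
            undirected.add(frozenset((u, v)))

    g = Graph(nodes=all_labels)
    for key in undirected:
        u, v = tuple(key)
        g.add_edge(u, v)
    result = largest_component(g)
    return PreprocessReport(
        nodes_removed=len(all_labels) - result.n_nodes,
        edges_removed=len(records) - result.n_edges,
        made_undirected=made_undirected,
        result=result,
    )


def density(g: Graph) -> float:
    """Edge density 2M / (N(N-1)); undefined for N < 2."""
    n = g.n_nodes
    if n < 2:
        raise GraphError("density undefined for graphs with fewer than 2 nodes")
    return 2.0 * g.n_edges / (n * (n - 1))
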