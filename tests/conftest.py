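"""Shared fixtures and random-graph helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from heatnet import Graph, fixture_toy15


@pytest.fixture(scope="session")
def toy():
    """The bundled 15-node / 19-edge example network."""
    return fixture_toy15()


@pytest.fixture()
def path5():
    return Graph([(1, 2), (2, 3), (3, 4), (4, 5)])


@pytest.fixture()
def k5():
    return complete_graph(5)


def complete_graph(n: int) -> Graph:
    return Graph([(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)])


def cycle_graph(n: int) -> Graph:
    return Graph([(i, i % n + 1) for i in range(1, n + 1)])


def random_connected_graph(rng: np.random.Generator, n: int, extra_p: float = 0.3) -> Graph:
    """Connected simple graph on nodes 1..n: random spanning tree + extras.

    Each arriving node attaches to a uniformly chosen earlier node
    (guaranteeing connectivity); every remaining pair is added
    independently with probability ``extra_p``.
    """
    edges = [(int(rng.integers(1, i)), i) for i in range(2, n + 1)]
    present = {frozenset(e) for e in edges}
    for i, j in itertools.combinations(range(1, n + 1), 2):
        if frozenset((i, j)) not in present and rng.random() < extra_p:
            edges.append((i, j))
            present.add(frozenset((i, j)))
    return Graph(edges)


def to_networkx(g: Graph):
    import networkx as nx

    gx = nx.Graph()
    gx.add_nodes_from(g.nodes)
    gx.add_edges_from(g.edges())
    return gx
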