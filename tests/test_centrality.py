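"""The five centrality measures against independent oracles and invariants."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heatnet import (
    Graph,
    GraphError,
    ConvergenceError,
    all_centralities,
    all_farness,
    betweenness_centrality,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    farness,
    heatmap_centrality,
)

from conftest import complete_graph, cycle_graph, random_connected_graph, to_networkx


def brute_force_betweenness(g: Graph) -> dict:
    """Betweenness by explicit enumeration of all shortest paths.

    Counts each unordered pair once, endpoints excluded; independent of
    the Brandes accumulation used by the implementation.
    """
    gx = to_networkx(g)
    bet = dict.fromkeys(g.nodes, 0.0)
    for j, k in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(gx, j, k))
        except nx.NetworkXNoPath:
            continue
        for interior in (p[1:-1] for p in paths):
            for v in interior:
                bet[v] += 1.0 / len(paths)
    return bet


class TestDegree:
    @pytest.mark.parametrize("node,expected", [(3, 6), (6, 5), (15, 1)])
    def test_toy_degrees(self, toy, node, expected):
        assert degree_centrality(toy)[node] == expected

    def test_path_middle_node(self, path5):
        assert degree_centrality(path5)[3] == 2


class TestEigenvector:
    def test_toy_values_match_dense_eigendecomposition(self, toy):
        cv = eigenvector_centrality(toy)
        mat, order = toy.adjacency_matrix()
        w, vecs = np.linalg.eigh(mat.toarray())
        e = vecs[:, np.argmax(w)]
        e = np.abs(e) / np.abs(e).max()
        for v, expected in zip(order, e):
            assert cv[v] == pytest.approx(expected, abs=1e-9)

    def test_toy_printed_values(self, toy):
        cv = eigenvector_centrality(toy)
        assert cv[3] == pytest.approx(1.0, abs=1e-12)
        assert round(cv[6], 3) == 0.919

    def test_structurally_symmetric_leaves_equal(self, toy):
        cv = eigenvector_centrality(toy)
        assert cv[1] == pytest.approx(cv[2], abs=1e-10)
        assert cv[11] == pytest.approx(cv[13], abs=1e-10)

    def test_eigen_residual_small(self, toy):
        cv = eigenvector_centrality(toy)
        mat, order = toy.adjacency_matrix()
        x = np.array([cv[v] for v in order])
        lam = (x @ (mat @ x)) / (x @ x)
        assert np.abs(mat @ x - lam * x).max() <= 1e-8

    def test_non_convergence_raises(self, path5):
        with pytest.raises(ConvergenceError):
            eigenvector_centrality(path5, max_iter=1)

    def test_disconnected_raises(self):
        with pytest.raises(GraphError):
            eigenvector_centrality(Graph([(1, 2), (3, 4)]))

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_dense_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(3, 40)))
        cv = eigenvector_centrality(g)
        mat, order = g.adjacency_matrix()
        w, vecs = np.linalg.eigh(mat.toarray())
        e = vecs[:, np.argmax(w)]
        e = np.abs(e) / np.abs(e).max()
        got = np.array([cv[v] for v in order])
        assert np.abs(got - e).max() < 1e-7


class TestCloseness:
    @pytest.mark.parametrize("node,far", [(6, 28), (15, 56), (3, 33)])
    def test_toy_closeness_is_reciprocal_farness(self, toy, node, far):
        assert closeness_centrality(toy)[node] == pytest.approx(1.0 / far)

    def test_two_node_path(self):
        g = Graph([(1, 2)])
        cv = closeness_centrality(g)
        assert cv[1] == 1.0 and cv[2] == 1.0

    def test_closeness_times_farness_is_one(self, toy):
        cv = closeness_centrality(toy)
        for v in toy.nodes:
            assert cv[v] * farness(toy, v) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_raises(self):
        with pytest.raises(GraphError):
            closeness_centrality(Graph([(1, 2), (3, 4)]))


class TestBetweenness:
    @pytest.mark.parametrize("node,expected", [(6, 55.5), (12, 13.0), (8, 48.0)])
    def test_toy_values(self, toy, node, expected):
        assert betweenness_centrality(toy)[node] == pytest.approx(expected)

    def test_leaves_have_zero_betweenness(self, toy):
        cv = betweenness_centrality(toy)
        for leaf in (1, 2, 11, 13, 14, 15):
            assert cv[leaf] == 0.0

    def test_matches_networkx_on_toy(self, toy):
        oracle = nx.betweenness_centrality(to_networkx(toy), normalized=False)
        cv = betweenness_centrality(toy)
        for v in toy.nodes:
            assert cv[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_disconnected_pairs_contribute_zero(self):
        g = Graph([(1, 2), (2, 3), (4, 5)])
        cv = betweenness_centrality(g)
        assert cv[2] == 1.0 and cv[4] == 0.0

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_brandes_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(2, 9)))
        cv = betweenness_centrality(g)
        oracle = brute_force_betweenness(g)
        for v in g.nodes:
            assert cv[v] == pytest.approx(oracle[v], abs=1e-9)


class TestHeatmap:
    def test_toy_node6(self, toy):
        cv = heatmap_centrality(toy)
        # farness 28 against neighbor mean (33+36+37+29+41)/5 = 176/5
        assert cv[6] == pytest.approx(28 - 176 / 5)
        assert cv[6] == pytest.approx(-7.2)

    def test_toy_node3(self, toy):
        assert round(heatmap_centrality(toy)[3], 3) == -6.667

    def test_all_toy_leaves_score_n_minus_2(self, toy):
        cv = heatmap_centrality(toy)
        for leaf in (1, 2, 11, 13, 14, 15):
            assert cv[leaf] == pytest.approx(13.0)

    def test_p3_hand_values(self):
        p3 = Graph([(1, 2), (2, 3)])
        cv = heatmap_centrality(p3)
        assert (cv[1], cv[2], cv[3]) == (pytest.approx(1), pytest.approx(-1), pytest.approx(1))

    def test_disconnected_raises(self):
        with pytest.raises(GraphError):
            heatmap_centrality(Graph([(1, 2), (3, 4)]))

    @settings(max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_leaf_law_and_degree_weighted_zero_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        g = random_connected_graph(rng, n, extra_p=float(rng.uniform(0, 0.5)))
        cv = heatmap_centrality(g)
        for v in g.nodes:
            if g.degree(v) == 1:
                assert cv[v] == pytest.approx(n - 2)
        weighted = sum(g.degree(v) * cv[v] for v in g.nodes)
        assert weighted == pytest.approx(0.0, abs=1e-8)


class TestAllCentralities:
    def test_p3_table(self):
        p3 = Graph([(1, 2), (2, 3)])
        cvs = all_centralities(p3)
        assert [cvs["degree"][v] for v in (1, 2, 3)] == [1, 2, 1]
        assert [cvs["betweenness"][v] for v in (1, 2, 3)] == [0.0, 1.0, 0.0]
        assert [cvs["heatmap"][v] for v in (1, 2, 3)] == [1.0, -1.0, 1.0]

    @pytest.mark.parametrize("g", [complete_graph(4), cycle_graph(6)],
                             ids=["K4", "C6"])
    def test_vertex_transitive_graphs_have_constant_measures(self, g):
        cvs = all_centralities(g)
        for cv in cvs.values():
            vals = list(cv.values.values())
            assert max(vals) == pytest.approx(min(vals), abs=1e-9)

    def test_shared_farness_consistent_with_direct_calls(self, toy):
        cvs = all_centralities(toy)
        direct_heat = heatmap_centrality(toy)
        direct_close = closeness_centrality(toy)
        for v in toy.nodes:
            assert cvs["heatmap"][v] == pytest.approx(direct_heat[v])
            assert cvs["closeness"][v] == pytest.approx(direct_close[v])

    def test_centrality_table_shape_and_ranks(self, toy):
        df = centrality_table(toy)
        assert len(df) == 15
        assert df.loc[df.node == 6, "heatmap_rank"].item() == 1
        assert df.loc[df.node == 3, "degree_rank"].item() == 1
        with pytest.raises(ValueError):
            centrality_table(toy, measures=("degree", "nope"))
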