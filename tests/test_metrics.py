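"""Topology metrics: frozen hand examples, oracle spot checks, invariants."""

import numpy as np
import networkx as nx
import pytest

from dkinet import (
    ThresholdedGraph,
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    efficiency,
    network_metrics,
    rewire_null,
    sigma_ratio,
    small_worldness,
)
from conftest import graph_from_edges
from oracles import (
    oracle_betweenness,
    oracle_clustering,
    oracle_efficiency,
    oracle_local_efficiency,
    oracle_lp,
)


class TestClustering:
    def test_complete_graph(self, k4):
        c, cp = clustering_coefficient(k4)
        assert np.allclose(c, 1.0) and cp == 1.0

    def test_star_has_no_triangles(self, star5):
        c, cp = clustering_coefficient(star5)
        assert np.all(c == 0) and cp == 0

    def test_triangle_plus_pendant(self):
        # triangle {0,1,2} with pendant 3-0: node values (1/3, 1, 1, 0)
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])
        c, cp = clustering_coefficient(g)
        assert np.allclose(c, [1 / 3, 1, 1, 0])
        assert cp == pytest.approx(7 / 12)


class TestPathsAndEfficiency:
    def test_complete_graph(self, k4):
        lp, n_inf = characteristic_path_length(k4)
        assert lp == 1.0 and n_inf == 0
        eg, eloc = efficiency(k4)
        assert eg == 1.0 and eloc == 1.0

    def test_path_graph(self, path4):
        lp, _ = characteristic_path_length(path4)
        assert lp == pytest.approx(10 / 6)
        eg, _ = efficiency(path4)
        assert eg == pytest.approx(13 / 18)

    def test_disconnected_uses_finite_pairs_only(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        lp, n_inf = characteristic_path_length(g)
        assert lp == 1.0
        assert n_inf == 8  # ordered cross-component pairs

    def test_edgeless_graph(self):
        g = graph_from_edges(3, [])
        with pytest.raises(ValueError, match="empty path set"):
            characteristic_path_length(g)
        eg, eloc = efficiency(g)
        assert eg == 0 and eloc == 0

    def test_weighted_distances_are_inverse_weights(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)], weights=[0.5, 0.25])
        lp, _ = characteristic_path_length(g)
        # distances: 2, 4, 6 -> mean 4
        assert lp == pytest.approx(4.0)


class TestBetweenness:
    def test_complete_graph_zero(self, k4):
        bi, b = betweenness(k4)
        assert np.all(bi == 0) and b == 0

    def test_star_center_carries_all_pairs(self, star5):
        bi, _ = betweenness(star5)
        assert bi[0] == pytest.approx(6.0)  # 6 leaf pairs via the center
        assert np.all(bi[1:] == 0)

    def test_path_midpoint(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        bi, _ = betweenness(g)
        assert bi[1] == pytest.approx(1.0)

    def test_tree_identity(self):
        # on a tree, sum(Bi) = sum over pairs (d(i,j) - 1)
        rng = np.random.default_rng(7)
        for seed in range(10):
            t = nx.random_labeled_tree(9, seed=int(rng.integers(1 << 30)))
            adj = nx.to_numpy_array(t)
            g = ThresholdedGraph(labels=[str(i) for i in range(9)],
                                 adjacency=adj, sparsity=1.0)
            bi, _ = betweenness(g)
            from dkinet.metrics import distance_matrix

            d = distance_matrix(g)
            iu = np.triu_indices(9, 1)
            assert bi.sum() == pytest.approx((d[iu] - 1).sum())


class TestOracleSpotChecks:
    """Small random graphs against the brute-force oracles (the exhaustive
    <=7-node sweep lives in the acceptance suite)."""

    @pytest.mark.parametrize("seed", range(10))
    def test_binary_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        adj = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = ThresholdedGraph(labels=[str(i) for i in range(n)], adjacency=adj,
                             sparsity=1.0)
        c, _ = clustering_coefficient(g)
        assert np.allclose(c, oracle_clustering(adj))
        bi, _ = betweenness(g)
        assert np.allclose(bi, oracle_betweenness(adj))
        eg, eloc = efficiency(g)
        assert eg == pytest.approx(oracle_efficiency(adj))
        assert eloc == pytest.approx(oracle_local_efficiency(adj))
        if adj.sum():
            lp, _ = characteristic_path_length(g)
            assert lp == pytest.approx(oracle_lp(adj))

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_of_lp_and_eg_under_edge_addition(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = nx.gnm_random_graph(10, 14, seed=seed)
        if not nx.is_connected(g):
            g = nx.compose(g, nx.path_graph(10))
        adj = nx.to_numpy_array(g)
        absent = [(i, j) for i in range(10) for j in range(i + 1, 10)
                  if adj[i, j] == 0]
        i, j = absent[int(rng.integers(len(absent)))]
        lp0 = characteristic_path_length(adj)[0]
        eg0 = efficiency(adj)[0]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1.0
        assert characteristic_path_length(adj2)[0] <= lp0 + 1e-12
        assert efficiency(adj2)[0] >= eg0 - 1e-12


class TestRewireNull:
    def test_degree_sequence_preserved(self):
        ws = nx.watts_strogatz_graph(30, 4, 0.2, seed=1)
        g = ThresholdedGraph(labels=[str(i) for i in range(30)],
                             adjacency=nx.to_numpy_array(ws), sparsity=60 / 435)
        nulls = rewire_null(g, n_rand=10, seed=3)
        deg = g.degrees()
        for null in nulls:
            assert np.array_equal(null.degrees(), deg)
            assert null.n_edges == g.n_edges
            assert np.all(np.diag(null.adjacency) == 0)

    def test_reproducible_from_seed(self):
        ws = nx.watts_strogatz_graph(20, 4, 0.2, seed=2)
        g = ThresholdedGraph(labels=[str(i) for i in range(20)],
                             adjacency=nx.to_numpy_array(ws), sparsity=40 / 190)
        a = rewire_null(g, n_rand=3, seed=9)
        b = rewire_null(g, n_rand=3, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.adjacency, y.adjacency)

    def test_triangle_returns_input_with_warning(self):
        g = graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])
        with pytest.warns(UserWarning, match="no valid"):
            nulls = rewire_null(g, n_rand=4, seed=0)
        for null in nulls:
            assert np.array_equal(null.adjacency, g.adjacency)

    def test_ring_lattice_nulls_lose_clustering(self):
        ring = nx.watts_strogatz_graph(50, 6, 0.0, seed=0)
        g = ThresholdedGraph(labels=[str(i) for i in range(50)],
                             adjacency=nx.to_numpy_array(ring),
                             sparsity=150 / 1225)
        cp = clustering_coefficient(g)[1]
        nulls = rewire_null(g, n_rand=20, seed=5)
        cp_null = np.mean([clustering_coefficient(x)[1] for x in nulls])
        assert cp_null < cp

    def test_weighted_nulls_keep_weight_multiset(self):
        rng = np.random.default_rng(8)
        ws = nx.watts_strogatz_graph(20, 4, 0.2, seed=3)
        adj = nx.to_numpy_array(ws) * rng.uniform(0.2, 1.0, size=(20, 20))
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = ThresholdedGraph(labels=[str(i) for i in range(20)], adjacency=adj,
                             sparsity=40 / 190, mode="weighted")
        null = rewire_null(g, n_rand=1, seed=1)[0]
        w0 = np.sort(g.adjacency[np.triu_indices(20, 1)])
        w1 = np.sort(null.adjacency[np.triu_indices(20, 1)])
        assert np.allclose(w0, w1)


class TestSmallWorldness:
    def test_sigma_identity_two_ways(self):
        ws = nx.watts_strogatz_graph(40, 6, 0.1, seed=1)
        g = ThresholdedGraph(labels=[str(i) for i in range(40)],
                             adjacency=nx.to_numpy_array(ws), sparsity=0.15)
        r = small_worldness(g, n_rand=20, seed=4)
        assert r.sigma == pytest.approx(r.gamma / r.lam, abs=1e-12)
        alt = (r.cp * r.lp_rand) / (r.cp_rand * r.lp)
        assert r.sigma == pytest.approx(alt, abs=1e-12)

    def test_watts_strogatz_is_small_world(self):
        ws = nx.watts_strogatz_graph(90, 6, 0.1, seed=7)
        g = ThresholdedGraph(labels=[str(i) for i in range(90)],
                             adjacency=nx.to_numpy_array(ws),
                             sparsity=270 / 4005)
        r = small_worldness(g, n_rand=30, seed=2)
        assert r.sigma > 1 and r.is_small_world

    def test_sigma_ratio_classifies_published_values(self):
        # e.g. a grey-matter mean-kurtosis network with sigma = 1.57
        assert sigma_ratio(1.57, 1.0) > 1

    def test_er_alternative_null_model(self):
        er = nx.gnm_random_graph(60, 300, seed=3)
        g = ThresholdedGraph(labels=[str(i) for i in range(60)],
                             adjacency=nx.to_numpy_array(er), sparsity=300 / 1770)
        nulls = rewire_null(g, n_rand=5, seed=1, model="er")
        for null in nulls:
            assert null.n_edges == 300

    def test_network_metrics_bundle_consistent(self, path4):
        m = network_metrics(path4)
        assert m.cp == clustering_coefficient(path4)[1]
        assert m.lp == characteristic_path_length(path4)[0]
        assert m.eg == efficiency(path4)[0]
        assert np.array_equal(m.degree, path4.degrees())
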