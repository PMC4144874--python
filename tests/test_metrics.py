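"""Weighted nodal/global graph metrics against hand values and brute force."""

import numpy as np
import pytest

import _oracles as oracles
from tractnet import (
    WeightedNetwork,
    betweenness,
    degree_and_strength,
    efficiencies,
    generalized_clustering,
    global_metrics,
    nodal_metrics,
    path_length_metrics,
    shortest_paths,
)


def net(w, labels=None):
    return WeightedNetwork(np.asarray(w, dtype=float), labels or ())


def star(n_leaves, weight=1.0):
    w = np.zeros((n_leaves + 1, n_leaves + 1))
    w[0, 1:] = w[1:, 0] = weight
    return net(w)


def triangle(w12, w13, w23):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[0, 2] = w[2, 0] = w13
    w[1, 2] = w[2, 1] = w23
    return net(w)


def complete(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return net(w)


class TestDegreeStrength:
    def test_empty_graph(self):
        k, s = degree_and_strength(net(np.zeros((4, 4))))
        assert np.all(k == 0) and np.all(s == 0)

    def test_star_hand_count(self):
        k, s = degree_and_strength(star(4))
        assert k[0] == 4 and s[0] == pytest.approx(4.0)
        assert np.all(k[1:] == 1) and np.allclose(s[1:], 1.0)

    def test_strength_is_row_sum(self, rng):
        w = oracles.random_weighted_graph(rng, 8)
        _, s = degree_and_strength(net(w))
        assert np.allclose(s, w.sum(axis=1))


class TestClustering:
    def test_triangle_free_graph_zero(self, path_net):
        c, c_g = generalized_clustering(path_net)
        assert np.all(c == 0) and c_g == 0

    def test_unit_triangle(self):
        c, c_g = generalized_clustering(triangle(1, 1, 1))
        assert np.allclose(c, 1.0) and c_g == pytest.approx(1.0)

    def test_cube_root_triple_product(self):
        # (1 * 8 * 27)^(1/3) = 6 at every corner of the triangle
        c, _ = generalized_clustering(triangle(1, 8, 27))
        assert np.allclose(c, 6.0)

    def test_matches_triangle_enumeration(self, rng):
        for _ in range(100):
            w = oracles.random_weighted_graph(rng, int(rng.integers(3, 7)))
            c, c_g = generalized_clustering(net(w))
            expected = oracles.clustering_onnela(w)
            assert np.allclose(c, expected)
            assert c_g == pytest.approx(expected.mean())

    def test_unit_weights_reduce_to_binary_clustering(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(20):
            w = (oracles.random_weighted_graph(rng, 7) > 0).astype(float)
            c, _ = generalized_clustering(net(w))
            expected = nx.clustering(nx.from_numpy_array(w))
            assert np.allclose(c, [expected[i] for i in range(7)])


class TestShortestPaths:
    def test_unit_path_distance(self, path_net):
        sp = shortest_paths(path_net)
        assert sp.distances[0, 2] == pytest.approx(2.0)

    def test_tied_paths_counted(self):
        # direct edge w=0.5 (length 2) ties with the two-hop unit route
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 1.0
        w[2, 1] = w[1, 2] = 1.0
        sp = shortest_paths(net(w))
        assert sp.distances[0, 1] == pytest.approx(2.0)
        assert sp.sigma[0, 1] == 2

    def test_matches_path_enumeration(self, rng):
        for _ in range(60):
            w = oracles.random_weighted_graph(rng, int(rng.integers(3, 7)))
            sp = shortest_paths(net(w))
            d, sigma, _ = oracles.all_pairs_shortest(w)
            assert np.allclose(sp.distances, d, equal_nan=False)
            assert np.array_equal(sp.sigma > 0, sigma > 0)
            assert np.allclose(sp.sigma, sigma)

    def test_distance_symmetry_and_triangle_inequality(self, rng):
        w = oracles.random_weighted_graph(rng, 8, connected=True)
        d = shortest_paths(net(w)).distances
        assert np.allclose(d, d.T)
        n = 8
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPathLengthMetrics:
    def test_complete_unit_graph(self):
        sp = shortest_paths(complete(5))
        l_i, l_g = path_length_metrics(sp)
        assert np.allclose(l_i, 1.0) and l_g == pytest.approx(1.0)

    def test_isolated_node_keeps_global_length_finite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        w[0, 2] = w[2, 0] = 1.0  # node 3 isolated
        l_i, l_g = path_length_metrics(shortest_paths(net(w)))
        assert np.isinf(l_i[0])  # arithmetic mean blows up
        assert np.isfinite(l_g)  # harmonic mean does not

    def test_three_cycle_with_weight_two(self):
        _, l_g = path_length_metrics(shortest_paths(triangle(2, 2, 2)))
        assert l_g == pytest.approx(0.5)

    def test_harmonic_mean_matches_oracle(self, rng):
        for _ in range(30):
            w = oracles.random_weighted_graph(rng, 6)
            _, l_g = path_length_metrics(shortest_paths(net(w)))
            d, _, _ = oracles.all_pairs_shortest(w)
            assert l_g == pytest.approx(oracles.harmonic_path_length(d))


class TestBetweenness:
    def test_complete_graph_zero(self):
        assert np.all(betweenness(shortest_paths(complete(5))) == 0)

    def test_path_center_counts_ordered_pairs(self, path_net):
        bc = betweenness(shortest_paths(path_net))
        assert bc[1] == pytest.approx(2.0)  # (a,c) and (c,a)
        assert bc[0] == bc[2] == 0

    def test_matches_path_enumeration(self, rng):
        for _ in range(60):
            w = oracles.random_weighted_graph(rng, int(rng.integers(3, 7)))
            bc = betweenness(shortest_paths(net(w)))
            _, _, expected = oracles.all_pairs_shortest(w)
            assert np.allclose(bc, expected)

    def test_twice_networkx_unordered_convention(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            w = oracles.random_weighted_graph(rng, 8, connected=True)
            g = nx.from_numpy_array(w)
            for _, _, d in g.edges(data=True):
                d["dist"] = 1.0 / d["weight"]
            expected = nx.betweenness_centrality(g, weight="dist", normalized=False)
            bc = betweenness(shortest_paths(net(w)))
            assert np.allclose(bc, [2 * expected[i] for i in range(8)])


class TestEfficiencies:
    def test_complete_unit_graph(self):
        e_glob, _ = efficiencies(complete(6))
        assert e_glob == pytest.approx(1.0)

    def test_empty_graph(self):
        assert efficiencies(net(np.zeros((5, 5)))) == (0.0, 0.0)

    def test_star_has_zero_local_efficiency(self):
        _, e_loc = efficiencies(star(5))
        assert e_loc == 0.0

    def test_matches_oracles(self, rng):
        for _ in range(25):
            w = oracles.random_weighted_graph(rng, 6)
            e_glob, e_loc = efficiencies(net(w))
            d, _, _ = oracles.all_pairs_shortest(w)
            assert e_glob == pytest.approx(oracles.global_efficiency(d))
            assert e_loc == pytest.approx(oracles.local_efficiency(w))


class TestMetricProperties:
    def test_permutation_equivariance(self, rng):
        w = oracles.random_weighted_graph(rng, 7, connected=True)
        perm = rng.permutation(7)
        table = nodal_metrics(net(w))
        permuted = nodal_metrics(net(w[np.ix_(perm, perm)]))
        for col in ("degree", "strength", "clustering", "mean_path_length", "betweenness"):
            assert np.allclose(permuted[col].to_numpy(),
                               table[col].to_numpy()[perm])

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_weight_scaling_laws(self, rng, c):
        w = oracles.random_weighted_graph(rng, 7, connected=True)
        base = nodal_metrics(net(w))
        scaled = nodal_metrics(net(c * w))
        assert np.array_equal(scaled["degree"], base["degree"])
        assert np.allclose(scaled["strength"], c * base["strength"])
        assert np.allclose(scaled["clustering"], c * base["clustering"])
        assert np.allclose(scaled["mean_path_length"], base["mean_path_length"] / c)
        assert np.allclose(scaled["betweenness"], base["betweenness"])
        g_base = global_metrics(net(w))
        g_scaled = global_metrics(net(c * w))
        assert g_scaled.path_length == pytest.approx(g_base.path_length / c)
        assert g_scaled.global_efficiency == pytest.approx(c * g_base.global_efficiency)
        assert g_scaled.local_efficiency == pytest.approx(c * g_base.local_efficiency)

    def test_global_metrics_consistent_with_parts(self, rng):
        w = oracles.random_weighted_graph(rng, 8, connected=True)
        g = global_metrics(net(w))
        c, c_g = generalized_clustering(net(w))
        e_glob, e_loc = efficiencies(net(w))
        _, l_g = path_length_metrics(shortest_paths(net(w)))
        assert g.clustering == pytest.approx(c_g)
        assert g.global_efficiency == pytest.approx(e_glob)
        assert g.local_efficiency == pytest.approx(e_loc)
        assert g.path_length == pytest.approx(l_g)
        assert g.path_length == pytest.approx(1.0 / g.global_efficiency)
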