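"""Motion screening, weight-matrix construction, averaging, backbone."""

import numpy as np
import pytest

import _oracles as oracles
from tractnet import (
    BackboneConfig,
    MotionLog,
    QCThresholds,
    TractCountSet,
    WeightedNetwork,
    average_networks,
    build_weight_matrix,
    extract_backbone,
    screen_motion,
)
from tractnet.network import DisconnectedGraphError


def log(params):
    return MotionLog(np.asarray(params, dtype=float), "s", "scan1")


class TestScreenMotion:
    def test_still_scan_is_kept(self):
        result = screen_motion(log(np.zeros((10, 6))))
        assert result.keep and result.reason is None

    def test_translation_over_one_mm_excludes(self):
        params = np.zeros((10, 6))
        params[4, 1] = 1.2  # mm
        params[:, 3:] = 0.2  # degrees, under threshold
        result = screen_motion(log(params))
        assert not result.keep
        assert result.reason == "translation"
        assert result.peak_translation == pytest.approx(1.2)

    def test_rotation_over_one_degree_excludes(self):
        params = np.zeros((10, 6))
        params[:, :3] = 0.9
        params[7, 5] = 1.5
        result = screen_motion(log(params))
        assert not result.keep
        assert result.reason == "rotation"

    def test_exactly_at_threshold_is_kept(self):
        params = np.zeros((5, 6))
        params[0, 0] = 1.0
        params[0, 3] = 1.0
        assert screen_motion(log(params)).keep

    def test_agrees_with_bruteforce_max(self, rng):
        thr = QCThresholds(0.8, 0.6)
        for _ in range(200):
            params = rng.normal(0, 0.5, size=(rng.integers(1, 20), 6))
            result = screen_motion(log(params), thr)
            expect_keep = (np.abs(params[:, :3]).max() <= 0.8
                           and np.abs(params[:, 3:]).max() <= 0.6)
            assert result.keep == expect_keep

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            MotionLog(np.zeros((0, 6)), "s", "scan1")


class TestBuildWeightMatrix:
    def test_zero_counts_give_zero_matrix(self):
        tc = TractCountSet(np.zeros((4, 4), dtype=int), np.full(4, 10), "s", "sc")
        net = build_weight_matrix(tc)
        assert np.all(net.weights == 0)

    def test_two_node_hand_computation(self):
        counts = np.zeros((2, 2), dtype=int)
        counts[0, 1] = 10  # seeded in region 1, voxels 5
        counts[1, 0] = 6   # seeded in region 2, voxels 3
        tc = TractCountSet(counts, np.array([5, 3]), "s", "sc")
        net = build_weight_matrix(tc)
        assert net.weights[0, 1] == pytest.approx(10 / 5 + 6 / 3)  # = 4.0
        assert net.weights[1, 0] == net.weights[0, 1]

    def test_permutation_equivariance(self, rng):
        n = 6
        counts = rng.integers(0, 40, size=(n, n))
        np.fill_diagonal(counts, 0)
        voxels = rng.integers(5, 50, size=n)
        perm = rng.permutation(n)
        direct = build_weight_matrix(TractCountSet(counts, voxels, "s", "sc")).weights
        permuted = build_weight_matrix(
            TractCountSet(counts[np.ix_(perm, perm)], voxels[perm], "s", "sc")
        ).weights
        assert np.allclose(permuted, direct[np.ix_(perm, perm)])

    def test_zero_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            TractCountSet(np.zeros((3, 3), dtype=int), np.array([5, 0, 3]), "s", "sc")

    def test_self_connections_excluded(self, rng):
        # build ignores whatever sits on the diagonal of raw directed counts
        counts = rng.integers(0, 20, size=(5, 5))
        np.fill_diagonal(counts, 0)
        voxels = rng.integers(5, 20, size=5)
        base = build_weight_matrix(TractCountSet(counts, voxels, "s", "sc"))
        assert np.all(np.diagonal(base.weights) == 0)


class TestAverageNetworks:
    def test_single_network_is_identity(self, path_net):
        assert np.array_equal(average_networks([path_net]).weights, path_net.weights)

    def test_arithmetic_mean(self):
        a = WeightedNetwork(np.array([[0, 2.0], [2.0, 0]]))
        b = WeightedNetwork(np.array([[0, 6.0], [6.0, 0]]))
        assert average_networks([a, b]).weights[0, 1] == pytest.approx(4.0)

    def test_identical_networks_average_to_themselves(self, path_net):
        mean = average_networks([path_net] * 5)
        assert np.allclose(mean.weights, path_net.weights)

    def test_label_mismatch_rejected(self, path_net):
        other = WeightedNetwork(path_net.weights, ("x", "y", "z"))
        with pytest.raises(ValueError, match="label"):
            average_networks([path_net, other])


def dense_net(w):
    return WeightedNetwork(np.asarray(w, dtype=float))


class TestBackbone:
    def test_worked_four_node_example(self):
        # K=2 on 4 nodes -> 4 edges: MST {34, 12, 13} then heaviest rest {23}
        w = np.zeros((4, 4))
        pairs = {(0, 1): 5, (0, 2): 4, (0, 3): 1, (1, 2): 3, (1, 3): 2, (2, 3): 6}
        for (i, j), v in pairs.items():
            w[i, j] = w[j, i] = v
        bb = extract_backbone(dense_net(w), BackboneConfig(2))
        kept = {(i, j) for i, j, _ in bb.edge_list()}
        assert kept == {(0, 1), (0, 2), (1, 2), (2, 3)}

    def test_input_with_exact_edge_count_returned_unchanged(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[i, j] = w[j, i] = 1.0 + i
        bb = extract_backbone(dense_net(w), BackboneConfig(2))
        assert np.allclose(bb.weights, w)

    def test_edge_count_and_average_degree(self, rng):
        for n, k in [(10, 4), (9, 3), (7, 2.5)]:
            w = oracles.random_weighted_graph(rng, n, density=0.8, connected=True)
            bb = extract_backbone(dense_net(w), BackboneConfig(k))
            assert bb.n_edges == int(np.floor(n * k / 2))

    def test_mst_weight_matches_bruteforce(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 8))
            w = oracles.random_weighted_graph(rng, n, density=0.7, connected=True)
            edges = [(i, j, w[i, j]) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
            target = n - 1  # backbone at minimal K is exactly an MST
            bb = extract_backbone(dense_net(w), BackboneConfig(2 * (n - 1) / n))
            assert bb.weights.sum() / 2 == pytest.approx(
                oracles.max_spanning_tree_weight(n, edges)
            )

    def test_backbone_is_optimal_spanning_superset(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 7))
            w = oracles.random_weighted_graph(rng, n, density=0.9, connected=True)
            edges = [(i, j, w[i, j]) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
            k = 2.5
            size = int(np.floor(n * k / 2))
            if len(edges) < size:
                continue
            bb = extract_backbone(dense_net(w), BackboneConfig(k))
            assert bb.weights.sum() / 2 == pytest.approx(
                oracles.best_spanning_superset_weight(n, edges, size)
            )

    def test_matches_networkx_maximum_spanning_tree(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(10):
            n = 8
            w = oracles.random_weighted_graph(rng, n, density=0.7, connected=True)
            g = nx.from_numpy_array(w)
            expected = sum(d["weight"] for _, _, d in
                           nx.maximum_spanning_tree(g).edges(data=True))
            bb = extract_backbone(dense_net(w), BackboneConfig(2 * (n - 1) / n))
            assert bb.weights.sum() / 2 == pytest.approx(expected)

    def test_backbone_connected_and_contains_tree(self, rng):
        w = oracles.random_weighted_graph(rng, 12, density=0.6, connected=True)
        bb = extract_backbone(dense_net(w), BackboneConfig(4))
        # connectivity via oracle BFS resample helper logic
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in range(12):
                if bb.weights[u, v] > 0 and v not in seen:
                    seen.add(v)
                    stack.append(v)
        assert len(seen) == 12

    def test_disconnected_graph_error_names_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(DisconnectedGraphError) as err:
            extract_backbone(dense_net(w), BackboneConfig(1.5))
        assert len(err.value.components) == 2

    def test_too_few_edges_error_reports_count(self, path_net):
        with pytest.raises(ValueError, match="2 positive edges"):
            extract_backbone(path_net, BackboneConfig(2.0))

    def test_k_below_spanning_tree_rejected(self, path_net):
        with pytest.raises(ValueError, match="spanning tree"):
            extract_backbone(path_net, BackboneConfig(0.5))


class TestWeightedNetworkInvariants:
    def test_asymmetric_matrix_rejected(self):
        w = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            WeightedNetwork(w)

    def test_negative_weights_rejected(self):
        w = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            WeightedNetwork(w)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            WeightedNetwork(np.zeros((2, 2)), ("a", "a"))

    def test_diagonal_zeroed(self):
        w = np.eye(3) * 5
        assert np.all(WeightedNetwork(w).weights == 0)
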