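"""Graph metrics: distances, efficiencies, clustering, nulls, sparsity AUC."""
import numpy as np
import pytest

import richconn.metrics as m
from richconn.metrics import (
    compute_global_metrics,
    compute_nodal_metrics,
    distance_matrix,
    rewire_null,
    small_world_indices,
    sparsity_auc,
    sparsity_grid,
)
from richconn.netbuild import WeightedNetwork

import _oracles as oracle
from conftest import network_from_edges


def path3():
    return network_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0})


class TestDistances:
    def test_two_unit_hops(self):
        d = distance_matrix(path3())
        assert d[0, 2] == pytest.approx(2.0)

    def test_inverse_weight_length(self):
        net = network_from_edges(2, {(0, 1): 2.0})
        assert distance_matrix(net)[0, 1] == pytest.approx(0.5)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            w = oracle.random_weighted_graph(8, 0.4, rng)
            d = distance_matrix(WeightedNetwork(w))
            assert np.allclose(d, oracle.floyd_warshall(w), equal_nan=True)


class TestGlobalMetrics:
    def test_path_graph_efficiency_and_clustering(self):
        g = compute_global_metrics(path3())
        assert g.eg == pytest.approx(5.0 / 6.0)
        assert g.cp == 0.0

    def test_triangle(self):
        net = network_from_edges(3, {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0})
        g = compute_global_metrics(net)
        assert g.cp == pytest.approx(1.0)
        assert g.lp == pytest.approx(1.0)
        assert g.eg == pytest.approx(1.0)

    def test_empty_network_is_zero(self):
        g = compute_global_metrics(WeightedNetwork(np.zeros((5, 5))))
        assert (g.cp, g.lp, g.eg, g.eloc) == (0.0, 0.0, 0.0, 0.0)

    def test_uniform_complete_graph_closed_forms(self):
        n, w = 7, 0.8
        full = np.full((n, n), w) - w * np.eye(n)
        g = compute_global_metrics(WeightedNetwork(full))
        assert g.cp == pytest.approx(1.0)
        assert g.lp == pytest.approx(1.0 / w)
        assert g.eg == pytest.approx(w)
        assert g.eloc == pytest.approx(w)

    def test_matches_networkx_clustering(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(5):
            w = oracle.random_weighted_graph(9, 0.5, rng)
            g = nx.from_numpy_array(w)
            expected = nx.average_clustering(g, weight="weight", count_zeros=True)
            assert compute_global_metrics(WeightedNetwork(w)).cp == pytest.approx(expected, abs=1e-12)

    def test_eg_monotone_in_single_edge_weight(self, rng):
        w = oracle.random_weighted_graph(8, 0.4, rng)
        net = WeightedNetwork(w)
        base = compute_global_metrics(net).eg
        i, j = np.argwhere(w > 0)[0]
        w2 = w.copy()
        w2[i, j] = w2[j, i] = w[i, j] * 2
        assert compute_global_metrics(WeightedNetwork(w2)).eg >= base

    def test_nodal_metrics_against_oracle(self, rng):
        w = oracle.random_weighted_graph(8, 0.5, rng)
        nm = compute_nodal_metrics(WeightedNetwork(w))
        assert np.allclose(nm["nodal_efficiency"], oracle.nodal_efficiency(w), atol=1e-12)
        assert np.array_equal(nm["degree"], oracle.degrees(w))


class TestRewireNull:
    def test_degree_sequence_and_weights_preserved(self, rng):
        w = oracle.random_weighted_graph(15, 0.3, rng)
        net = WeightedNetwork(w)
        for seed in range(20):
            null = rewire_null(net, seed=seed)
            assert np.array_equal(
                np.sort(m.binary_degrees(null.weights)), np.sort(m.binary_degrees(w))
            )
            iu = np.triu_indices(15, 1)
            assert np.allclose(
                np.sort(null.weights[iu][null.weights[iu] > 0]),
                np.sort(w[iu][w[iu] > 0]),
            )
            # degrees preserved per node, not just as a multiset
            assert np.array_equal(m.binary_degrees(null.weights), m.binary_degrees(w))

    def test_too_few_edges_returns_input_with_warning(self):
        net = network_from_edges(4, {(0, 1): 1.0})
        out = rewire_null(net, seed=0)
        assert out.flags.get("rewire_warning")
        assert np.array_equal(out.weights, net.weights)

    def test_rewiring_destroys_lattice_clustering(self):
        # ring lattice: each node tied to 2 neighbours either side -> high Cp
        n = 20
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        net = WeightedNetwork(w)
        base_cp = compute_global_metrics(net).cp
        null_cps = [
            compute_global_metrics(rewire_null(net, seed=s)).cp for s in range(10)
        ]
        assert np.mean(null_cps) <= base_cp


class TestSmallWorld:
    def test_sigma_is_gamma_over_lambda(self, rng):
        w = oracle.random_weighted_graph(16, 0.3, rng)
        sw = small_world_indices(WeightedNetwork(w), n_null=5, seed=3)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam)

    def test_watts_strogatz_like_network_is_small_world(self):
        # ring lattice (k=6 neighbours) with 10% of edges rewired
        n = 60
        rng = np.random.default_rng(99)
        w = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2, 3):
                j = (i + step) % n
                w[i, j] = w[j, i] = 1.0
        # rewire ~10% of edges, preserving degree via double swaps
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
        n_swap = int(0.05 * len(edges))  # each swap rewires two edges
        from richconn.metrics import _maslov_sneppen_edges
        ei, ej, _ = _maslov_sneppen_edges(
            [e[0] for e in edges], [e[1] for e in edges], n, n_swap, rng
        )
        w2 = np.zeros((n, n))
        for a, b in zip(ei, ej):
            w2[a, b] = w2[b, a] = 1.0
        sw = small_world_indices(WeightedNetwork(w2), n_null=20, seed=5)
        assert sw.sigma > 1
        assert sw.gamma > 1

    def test_self_normalization_is_near_unity(self, rng):
        w = oracle.random_weighted_graph(20, 0.3, rng)
        base = rewire_null(WeightedNetwork(w), seed=11)  # a draw from the ensemble
        sw = small_world_indices(base, n_null=60, seed=12)
        assert abs(sw.gamma - 1) <= 2 * sw.cp_null.std() / sw.cp_null.mean()
        assert abs(sw.lam - 1) <= 2 * sw.lp_null.std() / sw.lp_null.mean()


class TestSparsityAUC:
    def test_constant_and_linear_curves(self, monkeypatch, network_factory):
        net = network_factory(4, {(0, 1): 1.0, (1, 2): 0.5, (2, 3): 0.2})
        grid = sparsity_grid(0.10, 0.40, 0.01)
        calls = {"n": 0}

        def linear(_net):
            v = calls["n"] / (len(grid) - 1)
            calls["n"] += 1
            return v

        monkeypatch.setitem(m._METRIC_FUNCS, "const1", lambda _net: 1.0)
        monkeypatch.setitem(m._METRIC_FUNCS, "const0", lambda _net: 0.0)
        monkeypatch.setitem(m._METRIC_FUNCS, "linear", linear)
        assert sparsity_auc(net, "const1", grid).auc == pytest.approx(0.30)
        assert sparsity_auc(net, "const0", grid).auc == pytest.approx(0.0)
        assert sparsity_auc(net, "linear", grid).auc == pytest.approx(0.15)

    def test_unknown_metric_rejected(self, network_factory):
        with pytest.raises(ValueError):
            sparsity_auc(network_factory(3, {(0, 1): 1.0}), "betweenness")

    def test_curve_values_track_the_grid(self, rng):
        w = oracle.random_weighted_graph(12, 0.8, rng)
        curve = sparsity_auc(WeightedNetwork(w), "eg", sparsity_grid(0.1, 0.4, 0.05))
        assert len(curve.values) == len(curve.sparsity_grid)
        assert np.all(np.diff(curve.values) >= -1e-12)  # denser -> no less efficient
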