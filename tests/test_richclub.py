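"""Weighted rich-club coefficient, rich-node selection, edge classes."""
import numpy as np
import pytest

from richconn.netbuild import WeightedNetwork, build_network, group_consensus
from richconn.richclub import (
    binary_degree,
    classify_edges,
    identify_rich_nodes,
    normalized_rich_club,
    rich_club_coefficient,
    subject_class_strengths,
)
from richconn.metrics import rewire_null
from richconn.synthgen import SimulationConfig, generate_cohort

import _oracles as oracle
from conftest import network_from_edges


class TestBinaryDegree:
    def test_star(self):
        net = network_from_edges(5, {(0, i): 1.0 for i in range(1, 5)})
        assert list(binary_degree(net)) == [4, 1, 1, 1, 1]

    def test_empty(self):
        assert not binary_degree(WeightedNetwork(np.zeros((4, 4)))).any()

    def test_weights_are_ignored(self):
        net = network_from_edges(4, {(0, 1): 0.1, (0, 2): 9.0})
        assert binary_degree(net)[0] == 2


class TestRichClubCoefficient:
    def test_uniform_complete_graph_is_one(self):
        n = 6
        w = np.full((n, n), 2.0) - 2.0 * np.eye(n)
        net = WeightedNetwork(w)
        for k in range(5):
            assert rich_club_coefficient(net, k) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        # S = {b, c} at k=2; club weight 2; top-1 weight anywhere is 5
        net = network_from_edges(
            4, {(0, 1): 3, (0, 2): 2, (1, 2): 2, (2, 3): 1, (1, 3): 5}
        )
        assert rich_club_coefficient(net, 2) == pytest.approx(0.4)

    def test_empty_club_is_undefined(self):
        star = network_from_edges(5, {(0, i): 1.0 for i in range(1, 5)})
        assert np.isnan(rich_club_coefficient(star, 1))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            rich_club_coefficient(network_from_edges(3, {(0, 1): 1.0}), -1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            w = oracle.random_weighted_graph(int(rng.integers(4, 11)), 0.5, rng)
            net = WeightedNetwork(w)
            kmax = int(binary_degree(net).max(initial=0))
            for k in range(kmax + 1):
                got = rich_club_coefficient(net, k)
                want = oracle.phi_w(w, k)
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)
                    assert got <= 1 + 1e-12

    def test_directional_sensitivity(self):
        # weakening a club edge lowers phi at that k; changing a non-club
        # edge that stays outside the top-ranked weights leaves it unchanged
        edges = {(0, 1): 3.0, (0, 2): 2.0, (1, 2): 2.0, (2, 3): 1.0, (1, 3): 5.0}
        net = network_from_edges(4, edges)
        k = 2  # club = {1, 2}; phi = 2 / 5
        base = rich_club_coefficient(net, k)
        assert base == pytest.approx(0.4)
        weaker = {**edges, (1, 2): 1.0}
        assert rich_club_coefficient(network_from_edges(4, weaker), k) < base
        non_club_change = {**edges, (2, 3): 0.9}
        assert rich_club_coefficient(network_from_edges(4, non_club_change), k) == pytest.approx(base)


class TestNormalizedRichClub:
    def test_single_null_equals_that_draw(self, rng):
        w = oracle.random_weighted_graph(10, 0.5, rng)
        net = WeightedNetwork(w)
        curve = normalized_rich_club(net, n_null=1, seed=42)
        null = rewire_null(net, seed=np.random.default_rng(42))
        for idx, k in enumerate(curve.k_grid):
            want = rich_club_coefficient(null, int(k))
            got = curve.phi_null_mean[idx]
            assert (np.isnan(want) and np.isnan(got)) or got == pytest.approx(want)

    def test_self_normalization_near_unity(self, rng):
        w = oracle.random_weighted_graph(24, 0.35, rng)
        base = rewire_null(WeightedNetwork(w), seed=5)
        curve = normalized_rich_club(base, n_null=60, seed=6)
        mid = len(curve.k_grid) // 2
        ok = np.isfinite(curve.phi_norm[: mid + 1])
        dev = np.abs(curve.phi_norm[: mid + 1][ok] - 1)
        bound = 2 * curve.phi_null_sd[: mid + 1][ok] / curve.phi_null_mean[: mid + 1][ok]
        assert np.all(dev <= np.maximum(bound, 0.05))

    def test_planted_hubs_show_rich_club_organization(self, small_config):
        atlas, subjects = generate_cohort(small_config)
        controls = [
            build_network(raw, 1, atlas=atlas)
            for rec, raw in subjects if rec.group == "control"
        ]
        backbone = group_consensus(controls, 0.75).to_network()
        curve = normalized_rich_club(backbone, n_null=20, seed=3)
        above = np.nan_to_num(curve.phi_norm) > 1
        # a contiguous run of at least 3 k values with phi_norm > 1
        best = cur = 0
        for flag in above:
            cur = cur + 1 if flag else 0
            best = max(best, cur)
        assert best >= 3


class TestIdentifyRichNodes:
    def test_top_n_with_strength_tie_break(self):
        net = network_from_edges(
            5,
            {(0, 1): 1, (0, 2): 1, (0, 3): 1, (0, 4): 1, (1, 2): 1, (1, 3): 1,
             (2, 3): 5, (2, 4): 0.1, (3, 4): 0.1},
        )
        # degrees: [4, 3, 4, 4, 3]; the degree-4 tie is broken by strength,
        # so top-2 picks nodes 2 and 3 (strength 7.1) over node 0 (4.0)
        assert identify_rich_nodes(net, top_n=3) == frozenset({0, 2, 3})
        assert identify_rich_nodes(net, top_n=2) == frozenset({2, 3})

    def test_degree_cutoff_mode(self):
        # degrees 9 and 8 exceed k=7; degrees 2 and 1 do not
        n = 11
        w = np.zeros((n, n))
        for j in range(1, 10):
            w[0, j] = w[j, 0] = 1.0  # node 0: degree 9
        for j in [0, 2, 3, 4, 5, 6, 7, 8]:
            w[1, j] = w[j, 1] = 1.0  # node 1: degree 8
        net = WeightedNetwork(w)
        assert identify_rich_nodes(net, k=7) == frozenset({0, 1})

    def test_k_at_max_degree_gives_empty_set(self):
        net = network_from_edges(4, {(0, 1): 1.0, (1, 2): 1.0})
        assert identify_rich_nodes(net, k=int(binary_degree(net).max())) == frozenset()

    def test_exactly_one_selector_required(self):
        net = network_from_edges(3, {(0, 1): 1.0})
        with pytest.raises(ValueError):
            identify_rich_nodes(net)
        with pytest.raises(ValueError):
            identify_rich_nodes(net, k=1, top_n=2)


class TestClassifyEdges:
    def test_all_nodes_rich(self):
        net = network_from_edges(4, {(0, 1): 1.0, (2, 3): 2.0})
        cls = classify_edges(net, range(4))
        assert cls.class_strength["rich-club"] == pytest.approx(3.0)
        assert cls.class_strength["feeder"] == 0.0
        assert cls.class_strength["local"] == 0.0

    def test_no_rich_nodes(self):
        net = network_from_edges(4, {(0, 1): 1.0})
        cls = classify_edges(net, [])
        assert cls.class_strength["local"] == pytest.approx(1.0)
        assert np.isnan(cls.ratios["rich/feeder"])

    def test_hand_partition(self):
        net = network_from_edges(4, {(0, 1): 3.0, (0, 2): 2.0, (2, 3): 1.0})
        cls = classify_edges(net, [0, 1])
        assert cls.class_strength == {"rich-club": 3.0, "feeder": 2.0, "local": 1.0}
        assert cls.ratios["rich/feeder"] == pytest.approx(1.5)
        assert cls.ratios["rich/local"] == pytest.approx(3.0)
        assert cls.edge_class == {(0, 1): "rich-club", (0, 2): "feeder", (2, 3): "local"}

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError):
            classify_edges(network_from_edges(3, {(0, 1): 1.0}), [5])

    def test_partition_conserves_total_strength(self, rng):
        for _ in range(10):
            w = oracle.random_weighted_graph(9, 0.5, rng)
            net = WeightedNetwork(w)
            rich = rng.choice(9, size=3, replace=False)
            cls = classify_edges(net, rich)
            total = w[np.triu_indices(9, 1)].sum()
            assert sum(cls.class_strength.values()) == pytest.approx(total, abs=1e-12)


class TestSubjectClassStrengths:
    def test_identical_subjects_have_zero_variance(self, network_factory):
        net = network_factory(4, {(0, 1): 2.0, (1, 2): 1.0})
        df = subject_class_strengths([net] * 5, [0, 1])
        assert df.std().max() == 0.0

    def test_strengths_sum_to_subject_totals(self, small_config):
        atlas, subjects = generate_cohort(small_config)
        nets = [build_network(raw, 1, atlas=atlas) for _, raw in subjects[:6]]
        df = subject_class_strengths(nets, range(0, 14))
        for net, (_, row) in zip(nets, df.iterrows()):
            total = net.weights[np.triu_indices(net.n_nodes, 1)].sum()
            assert row.sum() == pytest.approx(total, abs=1e-10)

    def test_patient_rich_strength_lower_with_deficit(self):
        cfg = SimulationConfig(
            n_nodes=40, n_hubs=14, n_group1=20, n_group2=20,
            group_deficit=0.7, clinical_couplings=(), seed=21,
        )
        atlas, subjects = generate_cohort(cfg)
        nets = [build_network(raw, 1, atlas=atlas) for _, raw in subjects]
        groups = [rec.group for rec, _ in subjects]
        pat = [n for n, g in zip(nets, groups) if g == "patient"]
        con = [n for n, g in zip(nets, groups) if g == "control"]
        rich = identify_rich_nodes(group_consensus(con, 0.75).to_network(), top_n=14)
        s_pat = subject_class_strengths(pat, rich)["rich_club"].mean()
        s_con = subject_class_strengths(con, rich)["rich_club"].mean()
        assert s_pat < s_con
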