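"""Degree, hubs, wiring cost, thickness-by-degree and rich club."""

import math

import networkx as nx
import numpy as np
import pytest

from covnet import (degree_profile, hub_set, rich_club, rich_club_normalized,
                    thickness_by_degree, wiring_cost)
from covnet.synth import Subject

from conftest import net_from_adjacency


def _adj(edges, n):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return A


def _random_net(n, p, rng):
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return net_from_adjacency(nx.to_numpy_array(G) > 0)


class TestDegreeProfile:
    def test_four_node_path(self):
        net = net_from_adjacency(_adj([(0, 1), (1, 2), (2, 3)], 4))
        prof = degree_profile(net)
        assert prof.k.tolist() == [1, 2, 2, 1]
        assert prof.cumulative_at(1) == pytest.approx(1.0)
        assert prof.cumulative_at(2) == pytest.approx(0.5)
        assert prof.cumulative_at(3) == pytest.approx(0.0)

    def test_complete_k5(self):
        net = net_from_adjacency(~np.eye(5, dtype=bool))
        prof = degree_profile(net)
        assert np.all(prof.k == 4)
        assert prof.cumulative_at(4) == pytest.approx(1.0)
        assert prof.cumulative_at(5) == pytest.approx(0.0)

    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            net = _random_net(12, 0.4, rng)
            prof = degree_profile(net)
            for i in range(12):
                assert prof.k[i] == sum(net.A[i])
            assert prof.p.sum() == pytest.approx(1.0)
            assert np.all(np.diff(prof.P) <= 1e-12)  # non-increasing
            assert prof.cumulative_at(int(prof.k.min())) == pytest.approx(1.0)
            assert prof.k.sum() == 2 * net.n_edges


class TestHubSet:
    def test_star_center(self):
        edges = [(0, j) for j in range(1, 10)]
        prof = degree_profile(net_from_adjacency(_adj(edges, 10)))
        assert hub_set(prof, 0.1) == {1}

    def test_tie_rule_prefers_low_region_id(self):
        prof = degree_profile(net_from_adjacency(
            _adj([(0, 1), (1, 2), (2, 3), (3, 0)], 4)))
        assert hub_set(prof, 0.5) == {1, 2}

    def test_hub_count_at_paper_scale(self):
        rng = np.random.default_rng(1)
        net = _random_net(308, 0.1, rng)
        hubs = hub_set(degree_profile(net), 0.10)
        assert len(hubs) == 31  # ceil(0.10 * 308)

    def test_invariant_under_degree_preserving_relabeling(self):
        rng = np.random.default_rng(2)
        net = _random_net(15, 0.3, rng)
        prof = degree_profile(net)
        hubs = hub_set(prof, 0.2)
        n_hubs = math.ceil(0.2 * 15)
        cut = sorted(prof.k, reverse=True)[n_hubs - 1]
        assert all(prof.k[h - 1] >= cut for h in hubs)


class TestWiringCost:
    def test_triangle_sides(self):
        # 3-4-5 right triangle, fully connected: mean side length 4
        pts = np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0]], dtype=float)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        net = net_from_adjacency(~np.eye(3, dtype=bool))
        wc = wiring_cost(net, D)
        assert wc.wc == pytest.approx(4.0)
        assert wc.n_connections == 3

    def test_single_edge(self):
        D = np.array([[0.0, 7.0], [7.0, 0.0]])
        net = net_from_adjacency(_adj([(0, 1)], 2))
        assert wiring_cost(net, D).wc == pytest.approx(7.0)

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-50, 50, (12, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        for _ in range(20):
            net = _random_net(12, 0.4, rng)
            if net.n_edges == 0:
                continue
            total = sum(D[i, j] for i in range(12) for j in range(i + 1, 12)
                        if net.A[i, j])
            assert wiring_cost(net, D).wc == pytest.approx(total / net.n_edges)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-50, 50, (10, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        moved = pts @ q.T + np.array([5.0, -3.0, 11.0])
        D1 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        D2 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        net = _random_net(10, 0.4, rng)
        assert wiring_cost(net, D1).wc == pytest.approx(wiring_cost(net, D2).wc)

    def test_zero_edges_is_error(self):
        net = net_from_adjacency(np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            wiring_cost(net, np.zeros((4, 4)))


def _cohort(values, group="g"):
    return [Subject(subject_id=f"s{i}", group=group, site="x", values=v)
            for i, v in enumerate(np.atleast_2d(values))]


class TestThicknessByDegree:
    def test_uniform_thickness_is_flat(self):
        rng = np.random.default_rng(5)
        net = _random_net(20, 0.3, rng)
        curve = thickness_by_degree(net, _cohort(np.full((5, 20), 2.5)))
        assert np.allclose(curve["mean_value"], 2.5)

    def test_threshold_zero_is_overall_mean(self):
        rng = np.random.default_rng(6)
        net = _random_net(20, 0.3, rng)
        values = rng.uniform(2, 3, (5, 20))
        curve = thickness_by_degree(net, _cohort(values), mode="absolute")
        first = curve.iloc[0]
        assert first["degree_cutoff"] == net.degrees().min() or \
            first["degree_cutoff"] == 0
        overall = curve[curve["degree_cutoff"] == 0]
        if len(overall):
            assert overall["mean_value"].iloc[0] == \
                pytest.approx(values.mean(axis=0).mean())

    def test_planted_thin_hubs_give_decreasing_curve(self):
        rng = np.random.default_rng(7)
        net = _random_net(30, 0.25, rng)
        k = net.degrees().astype(float)
        # thickness decreases with degree: hubs planted thinner
        values = np.tile(3.0 - 0.05 * k, (6, 1))
        curve = thickness_by_degree(net, _cohort(values), mode="percentile")
        assert curve["mean_value"].iloc[-1] < curve["mean_value"].iloc[0]
        assert (curve["mean_value"].diff().dropna() <= 1e-9).all()

    def test_group_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        net = _random_net(10, 0.4, rng)
        net.group = "NT"
        with pytest.raises(ValueError):
            thickness_by_degree(net, _cohort(np.full((4, 10), 2.5), group="AUT"))


class TestRichClub:
    def test_complete_graph_is_one(self):
        net = net_from_adjacency(~np.eye(6, dtype=bool))
        phi = rich_club(net)
        assert phi and all(v == pytest.approx(1.0) for v in phi.values())

    def test_star_hand_enumeration(self):
        # S5: center degree 5, leaves degree 1; phi(0) = 2*5/(6*5) = 1/3
        net = net_from_adjacency(_adj([(0, j) for j in range(1, 6)], 6))
        phi = rich_club(net)
        assert phi[0] == pytest.approx(1 / 3)
        assert set(phi) == {0}  # only the center has degree > 1

    def test_matches_brute_force_and_networkx(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            net = _random_net(12, 0.4, rng)
            if net.n_edges == 0:
                continue
            phi = rich_club(net)
            k = net.degrees()
            for level, value in phi.items():
                nodes = [i for i in range(12) if k[i] > level]
                e = sum(net.A[i, j] for a, i in enumerate(nodes)
                        for j in nodes[a + 1:])
                assert value == pytest.approx(
                    2 * e / (len(nodes) * (len(nodes) - 1)))
            G = nx.from_numpy_array(net.A.astype(int))
            if nx.number_of_selfloops(G) == 0 and net.n_edges > 2:
                nx_phi = nx.rich_club_coefficient(G, normalized=False)
                for level in phi:
                    if level in nx_phi:
                        assert phi[level] == pytest.approx(nx_phi[level])

    def test_normalized_variant_defined_and_near_one_for_random(self):
        rng = np.random.default_rng(10)
        net = _random_net(30, 0.3, rng)
        norm = rich_club_normalized(net, n_rewires=20, rng_seed=1)
        assert norm
        mid = [v for k, v in norm.items() if k <= np.median(net.degrees())]
        assert np.allclose(mid, 1.0, atol=0.35)
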