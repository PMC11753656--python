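import itertools

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import LineString

from lintess.kfunction import (
    KFunctionConfig,
    KFunctionResult,
    NetworkDistances,
    PointPattern,
    classify,
    csr_envelope,
    k_observed,
    network_distances,
    network_k_analysis,
    planar_k,
    random_pattern,
)
from lintess.network import build_network

from conftest import random_network


def brute_force_point_distance(network, p1, p2):
    """Min total weight over all simple paths between two on-edge points,
    with each point inserted as a node splitting its edge."""
    g = nx.Graph()
    for e in network.edges.values():
        g.add_edge(("n", e.u), ("n", e.v), weight=e.length)
    for label, (eid, m) in (("p1", p1), ("p2", p2)):
        e = network.edges[eid]
        g.add_edge(("n", e.u), (label,), weight=m)
        g.add_edge((label,), ("n", e.v), weight=e.length - m)
    if p1[0] == p2[0]:
        g.add_edge(("p1",), ("p2",), weight=abs(p1[1] - p2[1]))
    best = np.inf
    for path in nx.all_simple_paths(g, ("p1",), ("p2",)):
        w = sum(g[a][b]["weight"] for a, b in zip(path, path[1:]))
        best = min(best, w)
    return best


class TestNetworkDistances:
    def test_two_points_on_one_edge(self, single_edge_network):
        pat = PointPattern.from_network(single_edge_network, [0, 0], [10.0, 50.0])
        d = network_distances(single_edge_network, pat)
        assert d[0, 1] == pytest.approx(40.0)

    def test_points_across_two_edges(self):
        net = build_network(
            [
                (LineString([(0, 0), (100, 0)]), {}),
                (LineString([(100, 0), (100, 100)]), {}),
            ]
        )
        pat = PointPattern.from_network(net, [0, 1], [60.0, 30.0])
        d = network_distances(net, pat)
        assert d[0, 1] == pytest.approx(40.0 + 30.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_network(rng, n_nodes=int(rng.integers(4, 8)),
                                 extra_edges=2)
            pat = random_pattern(net, 4, rng)
            d = network_distances(net, pat)
            for i, j in itertools.combinations(range(pat.n), 2):
                expected = brute_force_point_distance(
                    net,
                    (int(pat.edge_ids[i]), float(pat.measures[i])),
                    (int(pat.edge_ids[j]), float(pat.measures[j])),
                )
                assert d[i, j] == pytest.approx(expected)

    def test_metric_axioms(self, grid_network):
        pat = random_pattern(grid_network, 12, 3)
        d = network_distances(grid_network, pat)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_point_on_unknown_edge_rejected(self, single_edge_network):
        pat = PointPattern(np.array([[0.0, 0.0]]), np.array([99]),
                           np.array([1.0]))
        with pytest.raises(ValueError, match="unknown edge"):
            network_distances(single_edge_network, pat)


class TestKObserved:
    def test_single_edge_closed_form(self, single_edge_network):
        pat = PointPattern.from_network(single_edge_network, [0, 0], [10.0, 50.0])
        h = np.array([10.0, 39.9, 40.0, 100.0])
        k = k_observed(single_edge_network, pat, h)
        # rho = 2/100; K = 50 * mean_i N_i -> 0 below 40 m, 50 above
        assert k[0] == 0.0 and k[1] == 0.0
        assert k[2] == pytest.approx(50.0)
        assert k[3] == pytest.approx(50.0)

    def test_saturation_at_network_diameter(self, grid_network):
        pat = random_pattern(grid_network, 9, 5)
        l_t = grid_network.total_length
        k = k_observed(grid_network, pat, np.array([10.0, 10 * l_t]))
        assert k[-1] == pytest.approx(l_t * (pat.n - 1) / pat.n)

    def test_non_decreasing_in_h(self, grid_network):
        pat = random_pattern(grid_network, 20, 11)
        h = np.linspace(10, 1000, 40)
        k = k_observed(grid_network, pat, h)
        assert np.all(np.diff(k) >= 0)

    def test_fewer_than_two_points_rejected(self, grid_network):
        pat = random_pattern(grid_network, 1, 0)
        with pytest.raises(ValueError):
            k_observed(grid_network, pat, np.array([10.0]))


class TestRandomPattern:
    def test_length_proportional_allocation(self):
        net = build_network(
            [
                (LineString([(0, 0), (100, 0)]), {}),
                (LineString([(0, 10), (300, 10)]), {}),
            ]
        )
        n = 4000
        pat = random_pattern(net, n, 123)
        frac = np.mean(pat.edge_ids == 0)
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.25) < 3 * sigma

    def test_same_seed_reproduces(self, grid_network):
        p1 = random_pattern(grid_network, 25, 9)
        p2 = random_pattern(grid_network, 25, 9)
        assert np.array_equal(p1.edge_ids, p2.edge_ids)
        assert np.array_equal(p1.measures, p2.measures)

    def test_empty_pattern(self, grid_network):
        assert random_pattern(grid_network, 0, 1).n == 0

    def test_points_lie_on_their_edges(self, grid_network):
        pat = random_pattern(grid_network, 50, 2)
        for eid, m in zip(pat.edge_ids, pat.measures):
            assert 0.0 <= m <= grid_network.edges[int(eid)].length


class TestEnvelopes:
    def test_envelopes_bracket_mean(self, grid_network):
        cfg = KFunctionConfig(np.linspace(20, 600, 15), n_sim=30, seed=4)
        mean, lower, upper = csr_envelope(grid_network, 15, cfg)
        assert np.all(lower <= mean + 1e-12)
        assert np.all(mean <= upper + 1e-12)

    def test_single_replicate_collapses(self, grid_network):
        cfg = KFunctionConfig(np.linspace(20, 600, 10), n_sim=1, seed=4)
        mean, lower, upper = csr_envelope(grid_network, 10, cfg)
        assert mean == pytest.approx(lower)
        assert mean == pytest.approx(upper)

    def test_result_invariant_enforced(self):
        h = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="bracket"):
            KFunctionResult(h, np.zeros(2), np.zeros(2),
                            np.ones(2), np.full(2, 2.0))


class TestClassify:
    def test_above_upper_everywhere(self):
        labels = classify(np.array([10.0]), np.array([5.0]),
                          np.array([4.0]), np.array([6.0]))
        assert labels == ["significantly clustered"]

    def test_exact_mean_is_random(self):
        labels = classify(np.array([5.0]), np.array([5.0]),
                          np.array([4.0]), np.array([6.0]))
        assert labels == ["random"]

    def test_full_ladder(self):
        k = np.array([3.9, 4.5, 5.1, 5.9, 6.1])
        m, lo, up = np.full(5, 5.0), np.full(5, 4.0), np.full(5, 6.0)
        assert classify(k, m, lo, up) == [
            "significantly dispersed",
            "dispersed",
            "random",
            "clustered",
            "significantly clustered",
        ]

    def test_points_forced_onto_short_edge_detected_clustered(self, grid_network):
        # all points on a single 100 m edge of a 1200 m network
        pat = PointPattern.from_network(
            grid_network, np.zeros(12, int), np.linspace(5, 95, 12)
        )
        cfg = KFunctionConfig(np.linspace(20, 400, 10), n_sim=49, seed=8)
        res = network_k_analysis(grid_network, pat, cfg)
        assert res.labels[0] == "significantly clustered"
        assert res.labels[1] == "significantly clustered"


class TestPlanarK:
    def test_two_point_closed_form(self):
        pat = PointPattern.planar([(10.0, 10.0), (50.0, 10.0)])
        h = np.array([39.0, 40.0, 90.0])
        k = planar_k(pat, (0, 0, 100, 100), h)
        assert k[0] == 0.0
        assert k[1] == pytest.approx(5000.0)  # (10000/4)*2

    def test_csr_approaches_pi_h_squared(self):
        rng = np.random.default_rng(21)
        xy = rng.uniform(0, 1000, size=(800, 2))
        h = np.array([30.0, 60.0, 90.0])
        k = planar_k(PointPattern.planar(xy), (0, 0, 1000, 1000), h)
        assert k == pytest.approx(np.pi * h**2, rel=0.15)

    def test_point_outside_region_rejected(self):
        pat = PointPattern.planar([(10.0, 10.0), (500.0, 10.0)])
        with pytest.raises(ValueError, match="inside"):
            planar_k(pat, (0, 0, 100, 100), np.array([10.0]))


def test_distance_calculator_reused_across_patterns(grid_network):
    calc = NetworkDistances(grid_network)
    p1 = random_pattern(grid_network, 8, 1)
    p2 = random_pattern(grid_network, 8, 2)
    d1 = calc.pairwise(p1)
    assert d1 == pytest.approx(network_distances(grid_network, p1))
    assert calc.pairwise(p2).shape == (8, 8)
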