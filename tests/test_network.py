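import math

import numpy as np
import pytest

from mazenet.network import (ExplorationNetwork, StopEvent, build_network,
                             cca_cluster, detect_stops, measures,
                             trial_network_features)
from mazenet.synthetic import bm1_like_params, generate_trial

from conftest import make_traj
from graph_oracle import oracle_measures


def stop_at(xy, i=0):
    return StopEvent(np.asarray(xy, dtype=float), float(i), float(i) + 1.0, 20)


def net_from_sequence(coords):
    """Build a network from a temporal sequence of well-separated sites."""
    stops = [stop_at(c, i) for i, c in enumerate(coords)]
    centroids, members = cca_cluster(stops)
    return build_network(stops, centroids, members)


class TestDetectStops:
    def test_stationary_segment_amid_motion(self, bm1):
        pts = ([[i * 10.0, 0.0] for i in range(40)]
               + [[400.0, 0.0]] * 40
               + [[400.0 + i * 10.0, 0.0] for i in range(40)])
        stops = detect_stops(make_traj(pts), bm1)
        assert len(stops) == 1
        assert stops[0].centroid[0] == pytest.approx(400.0, abs=5.0)
        assert stops[0].n_frames >= 20

    def test_constant_speed_above_threshold_no_stops(self, bm1):
        # 5 mm/frame -> 95 mm per 20-frame window >= 40 mm
        pts = np.column_stack([5.0 * np.arange(200), np.zeros(200)])
        assert detect_stops(make_traj(pts), bm1) == []

    def test_slow_drift_below_threshold_is_a_stop(self, bm1):
        # 1 mm/frame -> 19 mm per window < 40 mm
        pts = np.column_stack([1.0 * np.arange(100), np.zeros(100)])
        stops = detect_stops(make_traj(pts), bm1)
        assert len(stops) == 1

    def test_two_stationary_segments_split_by_dash(self, bm1):
        pts = ([[0.0, 0.0]] * 30
               + [[i * 20.0, 0.0] for i in range(1, 21)]
               + [[400.0, 0.0]] * 30)
        stops = detect_stops(make_traj(pts), bm1)
        assert len(stops) == 2

    def test_window_shorter_than_trajectory(self, bm1):
        assert detect_stops(make_traj([[0, 0], [1, 1]]), bm1) == []


class TestCcaCluster:
    def test_two_close_stops_merge_at_midpoint(self):
        centroids, members = cca_cluster([stop_at((0, 0)), stop_at((30, 0))])
        assert len(members) == 1
        np.testing.assert_allclose(centroids[0], [15.0, 0.0])

    def test_two_distant_stops_stay_separate(self):
        centroids, members = cca_cluster([stop_at((0, 0)), stop_at((100, 0))])
        assert len(members) == 2
        np.testing.assert_allclose(centroids, [[0, 0], [100, 0]])

    def test_collinear_chain_reaches_fixed_point(self):
        """0/35/70 mm chain: whatever the converged partition, one more
        iteration changes nothing and centroids are exact member means."""
        stops = [stop_at((0, 0), 0), stop_at((35, 0), 1), stop_at((70, 0), 2)]
        centroids, members = cca_cluster(stops)
        coords = np.array([[0, 0], [35, 0], [70, 0]], dtype=float)
        for c, mem in zip(centroids, members):
            np.testing.assert_allclose(c, coords[mem].mean(axis=0))
        c2, m2 = cca_cluster(stops)  # deterministic
        assert [list(m) for m in members] == [list(m) for m in m2]

    def test_planted_clusters_recovered(self):
        """Well-separated planted clusters (gap > 2x merge radius) are
        recovered exactly, every stop within the radius of its centroid."""
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [300, 0], [0, 300], [250, 250]])
        stops, truth = [], []
        i = 0
        for k, c in enumerate(centers):
            for _ in range(6):
                stops.append(stop_at(c + rng.uniform(-12, 12, 2), i))
                truth.append(k)
                i += 1
        centroids, members = cca_cluster(stops)
        assert len(members) == 4
        for c, mem in zip(centroids, members):
            assert len({truth[i] for i in mem}) == 1
            for i in mem:
                assert np.linalg.norm(stops[i].centroid - c) < 40.0

    def test_empty_input(self):
        centroids, members = cca_cluster([])
        assert len(centroids) == 0 and members == []


class TestBuildNetwork:
    def test_self_transitions_make_no_links(self):
        net = net_from_sequence([(0, 0), (1, 0), (0, 1)])  # one node, 3 stops
        assert net.order == 1 and len(net.links) == 0

    def test_back_and_forth_deduplicates(self):
        net = net_from_sequence([(0, 0), (200, 0), (0, 0), (200, 0)])
        assert net.order == 2 and len(net.links) == 1

    def test_cycle_makes_triangle(self):
        net = net_from_sequence([(0, 0), (200, 0), (0, 200), (0, 0)])
        assert net.order == 3 and len(net.links) == 3


class TestMeasures:
    def test_triangle(self):
        m = measures(net_from_sequence([(0, 0), (200, 0), (0, 200), (0, 0)]))
        assert m.density == 1.0
        assert m.clustering == 1.0
        assert m.shortest_path == 1.0
        assert m.betweenness == 0.0

    def test_path_graph(self):
        m = measures(net_from_sequence([(0, 0), (200, 0), (400, 0)]))
        assert m.degree == pytest.approx(4 / 3)
        assert m.density == pytest.approx(2 / 3)
        assert m.betweenness == pytest.approx(1 / 3)  # (0 + 1 + 0)/3

    def test_star_with_four_leaves(self):
        seq = [(0, 0), (200, 0), (0, 0), (-200, 0), (0, 0), (0, 200),
               (0, 0), (0, -200)]
        m = measures(net_from_sequence(seq))
        assert m.density == pytest.approx(0.4)
        # center closeness 1/4; each leaf 1/(1+2*3)=1/7
        assert m.closeness == pytest.approx((1 / 4 + 4 / 7) / 5)

    def test_empty_network_is_all_nan(self):
        m = measures(ExplorationNetwork(np.empty((0, 2)), (), frozenset(), ()))
        assert m.order == 0
        assert math.isnan(m.density) and math.isnan(m.closeness)

    def test_oracle_equivalence_on_random_graphs(self):
        """degree/density/clustering/shortest-path/betweenness/closeness
        agree with the exhaustive path-enumeration oracle on random graphs
        of up to 8 nodes, including disconnected ones."""
        rng = np.random.default_rng(9)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.4]
            net = ExplorationNetwork(
                np.zeros((n, 2)), tuple((i,) for i in range(n)),
                frozenset(frozenset(e) for e in edges), tuple(range(n)))
            got = measures(net)
            want = oracle_measures(n, edges)
            for key, expected in want.items():
                value = getattr(got, key)
                if expected is None:
                    assert math.isnan(value)
                else:
                    assert value == pytest.approx(expected, abs=1e-9), key

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        n = 7
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.5]
        perm = rng.permutation(n)
        relabeled = [(int(perm[i]), int(perm[j])) for i, j in edges]
        nets = [ExplorationNetwork(np.zeros((n, 2)),
                                   tuple((i,) for i in range(n)),
                                   frozenset(frozenset(e) for e in es),
                                   tuple(range(n)))
                for es in (edges, relabeled)]
        a, b = (measures(x) for x in nets)
        for key in ("degree", "density", "clustering", "shortest_path",
                    "betweenness", "closeness"):
            assert getattr(a, key) == pytest.approx(getattr(b, key))


class TestTrialNetworkFeatures:
    def test_no_stops_gives_empty_network(self, bm1):
        pts = np.column_stack([6.0 * np.arange(100), np.zeros(100)])
        m = trial_network_features(make_traj(pts), bm1)
        assert m.n_stops == 0 and m.order == 0

    def test_three_site_cycle_is_a_triangle(self, bm1):
        pts = []
        sites = [(0.0, 0.0), (300.0, 0.0), (0.0, 300.0), (0.0, 0.0)]
        for a, b in zip(sites, sites[1:]):
            pts += [list(a)] * 30
            seg = np.linspace(a, b, 15)
            pts += seg.tolist()
        pts += [list(sites[-1])] * 30
        m = trial_network_features(make_traj(pts), bm1)
        assert m.order == 3
        assert m.density == 1.0

    def test_home_base_has_maximal_betweenness(self, bm1):
        """Roundtrip exploration organized around one site yields a network
        whose base node carries the highest betweenness."""
        import networkx as nx
        traj = generate_trial(
            bm1_like_params(seed=21, home_base_roundtrips=6), bm1)
        stops = detect_stops(traj, bm1)
        centroids, members = cca_cluster(stops)
        net = build_network(stops, centroids, members)
        assert net.order >= 3
        bc = nx.betweenness_centrality(net.graph())
        best = max(bc, key=bc.get)
        counts = [len(m) for m in net.members]
        assert counts[best] == max(counts)  # the busiest site relays most


def test_scaled_stop_pattern_never_merges_more(bm1):
    """x3-scaled stop coordinates with the merge radius fixed at 40 mm can
    only split clusters, never merge them — larger arenas make larger
    networks."""
    rng = np.random.default_rng(11)
    coords = rng.uniform(-200, 200, (30, 2))
    stops = [stop_at(c, i) for i, c in enumerate(coords)]
    scaled = [stop_at(c * 3.0, i) for i, c in enumerate(coords)]
    _, members = cca_cluster(stops)
    _, members3 = cca_cluster(scaled)
    assert len(members3) >= len(members)
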