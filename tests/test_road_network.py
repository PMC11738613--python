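import itertools

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import LineString

from twosfca.gis_io import RoadLayer, RoadSegment
from twosfca.road_network import (
    DEFAULT_SPEEDS_KMH,
    ODMatrix,
    SpeedTable,
    build_graph,
    edge_travel_time_min,
    nearest_facility,
    od_cost_matrix,
    snap_points,
)
from twosfca.synthetic_province import ProvinceSpec, generate_province


def layer(*segs):
    return RoadLayer(list(segs))


def seg(sid, coords, cls="arterial"):
    return RoadSegment(sid, LineString(coords), cls)


class TestSpeedTable:
    def test_defaults_match_nine_class_table(self):
        t = SpeedTable()
        assert t["highway"] == 100
        assert t["expressway"] == 80
        assert t["arterial"] == 60
        assert t["feeder"] == 20
        assert t["other"] == 20
        assert t["internal"] == 20
        assert t["rural"] == 30
        assert t["bicycle"] == 15
        assert t["pedestrian"] == 5

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            SpeedTable({"arterial": 60})

    def test_nonpositive_speed_rejected(self):
        bad = dict(DEFAULT_SPEEDS_KMH, rural=0.0)
        with pytest.raises(ValueError, match="non-positive"):
            SpeedTable(bad)


class TestBuildGraph:
    def test_1km_arterial_is_one_minute(self):
        net = build_graph(layer(seg("a", [(0, 0), (1000, 0)], "arterial")))
        (_, _, data), = net.graph.edges(data=True)
        assert data["time_min"] == pytest.approx(1.0)

    def test_5km_pedestrian_is_sixty_minutes(self):
        net = build_graph(layer(seg("p", [(0, 0), (5000, 0)], "pedestrian")))
        (_, _, data), = net.graph.edges(data=True)
        assert data["time_min"] == pytest.approx(60.0)

    def test_shared_endpoint_merges_to_degree_two_node(self):
        net = build_graph(layer(
            seg("a", [(0, 0), (1000, 0)]),
            seg("b", [(1000, 0), (2000, 0)]),
        ))
        assert net.n_nodes == 3
        degrees = sorted(d for _, d in net.graph.degree())
        assert degrees == [1, 1, 2]

    def test_vertices_within_tolerance_merge(self):
        net = build_graph(layer(
            seg("a", [(0, 0), (1000, 0)]),
            seg("b", [(1000 + 1e-8, 0), (2000, 0)]),
        ))
        assert net.n_nodes == 3

    def test_zero_length_segment_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            net = build_graph(layer(
                seg("ok", [(0, 0), (1000, 0)]),
                seg("zero", [(500, 500), (500, 500)]),
            ))
        assert net.graph.number_of_edges() == 1
        assert "zero-length" in caplog.text

    def test_time_equals_length_over_speed(self):
        assert edge_travel_time_min(1000, 60) == pytest.approx(1.0)
        assert edge_travel_time_min(40000, 80) == pytest.approx(30.0)


class TestSnapPoints:
    @pytest.fixture()
    def net(self):
        return build_graph(layer(
            seg("h", [(0, 0), (1000, 0), (2000, 0)]),
            seg("v", [(1000, 0), (1000, 1000)]),
        ))

    def test_coincident_point_snaps_with_zero_distance(self, net):
        res = snap_points(np.array([[1000.0, 0.0]]), net)
        assert res.snap_dist_m[0] == 0.0
        assert np.allclose(net.node_xy[res.node_ids[0]], [1000, 0])

    def test_equidistant_tie_goes_to_lower_node_id(self, net):
        # (500, 300) is exactly halfway between nodes (0,0) and (1000,0)
        res = snap_points(np.array([[500.0, 300.0]]), net)
        winner = res.node_ids[0]
        d = np.hypot(*(net.node_xy - [500, 300]).T)
        tied = np.flatnonzero(np.abs(d - d.min()) <= 1e-9)
        assert winner == tied.min()

    def test_beyond_max_snap_flagged(self, net):
        res = snap_points(np.array([[0.0, 99999.0]]), net, max_snap_m=5000)
        assert res.node_ids[0] == -1
        assert not res.reachable[0]

    def test_matches_bruteforce_nearest_scan(self):
        bundle = generate_province(ProvinceSpec(seed=3, n_facilities=5))
        net = build_graph(bundle.roads)
        rng = np.random.default_rng(99)
        pts = rng.uniform([0, 0], [20000, 20000], size=(100, 2))
        res = snap_points(pts, net)
        for p, nid in zip(pts, res.node_ids):
            d = np.hypot(*(net.node_xy - p).T)
            best = d.min()
            tied = np.flatnonzero(np.abs(d - best) <= 1e-9)
            assert nid == tied.min()


def grid_network():
    """12-node 4x3 grid with mixed classes for oracle comparison."""
    segs = []
    classes = itertools.cycle(["arterial", "rural", "feeder", "expressway"])
    for r in range(3):
        for c in range(4):
            x, y = c * 1000.0, r * 1000.0
            if c < 3:
                segs.append(seg(f"h{r}{c}", [(x, y), (x + 1000, y)], next(classes)))
            if r < 2:
                segs.append(seg(f"v{r}{c}", [(x, y), (x, y + 1000)], next(classes)))
    return build_graph(layer(*segs))


class TestODMatrix:
    def test_co_located_pair_is_zero(self):
        net = grid_network()
        od = od_cost_matrix(net, np.array([0, 5]), np.array([0]), ["p0", "p1"], ["F0"])
        assert od.time_min[0, 0] == 0.0
        assert od.dist_km[0, 0] == 0.0

    def test_triangle_prefers_two_fast_edges(self):
        # direct pedestrian edge (3 km at 5 km/h = 36 min) vs two arterial
        # edges (2 x 2 km at 60 km/h = 4 min)
        net = build_graph(layer(
            seg("direct", [(0, 0), (3000, 0)], "pedestrian"),
            seg("up", [(0, 0), (1500, 2000)], "arterial"),
            seg("down", [(1500, 2000), (3000, 0)], "arterial"),
        ))
        snap = snap_points(np.array([[0.0, 0.0], [3000.0, 0.0]]), net)
        od = od_cost_matrix(net, snap.node_ids[:1], snap.node_ids[1:], ["p"], ["F"])
        assert od.time_min[0, 0] == pytest.approx(5.0)  # 2 x 2.5 km at 60
        assert od.dist_km[0, 0] == pytest.approx(5.0)

    def test_all_pairs_match_floyd_warshall_oracle(self):
        net = grid_network()
        demand_nodes = np.arange(net.n_nodes)
        facility_nodes = np.array([0, 5, 11])
        od = od_cost_matrix(net, demand_nodes, facility_nodes,
                            [f"p{i}" for i in demand_nodes], ["F0", "F1", "F2"])
        oracle = nx.floyd_warshall_numpy(net.graph, weight="time_min")
        for i in demand_nodes:
            for j, fnode in enumerate(facility_nodes):
                assert od.time_min[i, j] == pytest.approx(oracle[i, fnode], abs=1e-9)

    def test_unreachable_pair_is_inf(self):
        net = build_graph(layer(
            seg("a", [(0, 0), (1000, 0)]),
            seg("b", [(50000, 50000), (51000, 50000)]),
        ))
        snap = snap_points(np.array([[0.0, 0.0], [50000.0, 50000.0]]), net)
        od = od_cost_matrix(net, snap.node_ids[:1], snap.node_ids[1:], ["p"], ["F"])
        assert np.isinf(od.time_min[0, 0])

    def test_unsnapped_point_rows_are_inf(self):
        net = grid_network()
        od = od_cost_matrix(net, np.array([-1, 0]), np.array([0]), ["p0", "p1"], ["F0"])
        assert np.isinf(od.time_min[0, 0])
        assert od.time_min[1, 0] == 0.0

    def test_triangle_inequality_on_shortest_path_metric(self):
        net = grid_network()
        nodes = np.arange(net.n_nodes)
        ids = [f"n{i}" for i in nodes]
        od = od_cost_matrix(net, nodes, nodes, ids, ids)
        t = od.time_min
        for i in range(len(nodes)):
            for j in range(len(nodes)):
                for k in range(len(nodes)):
                    assert t[i, k] <= t[i, j] + t[j, k] + 1e-9

    def test_speed_monotonicity_and_exact_scaling(self):
        bundle = generate_province(ProvinceSpec(seed=2, n_facilities=4))
        net1 = build_graph(bundle.roads)
        faster = SpeedTable({c: 2 * s for c, s in DEFAULT_SPEEDS_KMH.items()})
        net2 = build_graph(bundle.roads, faster)
        nodes = np.arange(0, net1.n_nodes, 7)
        ids = [f"n{i}" for i in nodes]
        od1 = od_cost_matrix(net1, nodes, nodes[:3], ids, ids[:3])
        od2 = od_cost_matrix(net2, nodes, nodes[:3], ids, ids[:3])
        assert np.allclose(od2.time_min, od1.time_min / 2.0)
        # raising one class's speed never increases any time
        bumped = SpeedTable(dict(DEFAULT_SPEEDS_KMH, rural=90.0))
        od3 = od_cost_matrix(build_graph(bundle.roads, bumped), nodes, nodes[:3],
                             ids, ids[:3])
        assert np.all(od3.time_min <= od1.time_min + 1e-9)


class TestNearestFacility:
    def make_od(self, times):
        times = np.asarray(times, dtype=float)
        n, m = times.shape
        return ODMatrix(
            point_ids=[f"p{i}" for i in range(n)],
            facility_ids=[f"F{j}" for j in range(m)],
            time_min=times, dist_km=times.copy(),
        )

    def test_single_facility_always_nearest(self):
        od = self.make_od([[3.0], [7.5]])
        ids, mins = nearest_facility(od)
        assert list(ids) == ["F0", "F0"]

    def test_argmin_example(self):
        od = self.make_od([[17.2, 9.4, 31.0]])
        ids, mins = nearest_facility(od)
        assert ids[0] == "F1"
        assert mins[0] == pytest.approx(9.4)

    def test_tie_breaks_to_lower_facility_id(self):
        od = self.make_od([[5.0, 5.0, 9.0]])
        ids, _ = nearest_facility(od, ["F2", "F1", "F0"])
        # F0 and F1 tie at 5.0 -> F0 wins
        assert ids[0] == "F0"

    def test_empty_subset_is_error(self):
        od = self.make_od([[1.0]])
        with pytest.raises(ValueError, match="empty"):
            nearest_facility(od, [])

    def test_unreachable_point_flagged(self):
        od = self.make_od([[np.inf, np.inf]])
        ids, mins = nearest_facility(od)
        assert ids[0] is None
        assert np.isinf(mins[0])

    def test_subset_matches_bruteforce_column_min(self, province7_result, province7):
        od = province7_result.od
        subset = [f.facility_id for f in province7.facilities
                  if "hyalys" in f.stocked_types]
        ids, mins = nearest_facility(od, subset)
        cols = [od.facility_ids.index(f) for f in sorted(subset)]
        brute = od.time_min[:, cols].min(axis=1)
        assert np.allclose(mins, brute)
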