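"""Routable travel-time graph, OD cost matrix and nearest-facility costs.

The road layer becomes an undirected graph whose nodes are polyline
vertices (merged when coincident within 1e-6 m) and whose edges carry
length, road class and travel time ``length_km / speed_kmh * 60`` minutes.
Shortest paths minimise travel time; the network distance reported for a
pair is measured along that time-optimal path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .gis_io import Facility, RoadLayer, ROAD_CLASSES

logger = logging.getLogger(__name__)

#: Default travel speed (km/h) per canonical road class.
DEFAULT_SPEEDS_KMH = {
    "highway": 100.0,
    "expressway": 80.0,
    "arterial": 60.0,
    "feeder": 20.0,
    "other": 20.0,
    "internal": 20.0,
    "rural": 30.0,
    "bicycle": 15.0,
    "pedestrian": 5.0,
}

#: Default maximum snapping distance from a point to its nearest graph node (m).
DEFAULT_MAX_SNAP_M = 5000.0

_MERGE_DECIMALS = 6  # coordinates equal within 1e-6 m collapse to one node


@dataclass(frozen=True)
class SpeedTable:
    """Mapping road class -> travel speed in km/h; all nine classes required."""

    speeds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPEEDS_KMH))

    def __post_init__(self) -> None:
        missing = set(ROAD_CLASSES) - set(self.speeds)
        if missing:
            raise ValueError(f"speed table missing classes: {sorted(missing)}")
        bad = {c: s for c, s in self.speeds.items() if s <= 0}
        if bad:
            raise ValueError(f"non-positive speeds: {bad}")

    def __getitem__(self, road_class: str) -> float:
        return self.speeds[road_class]


@dataclass
class TravelNetwork:
    """Undirected travel graph with node coordinates and a KD-tree for snapping."""

    graph: nx.Graph
    node_xy: np.ndarray  # (n_nodes, 2); row index == node id

    def __post_init__(self) -> None:
        self._tree = cKDTree(self.node_xy) if len(self.node_xy) else None

    @property
    def n_nodes(self) -> int:
        return len(self.node_xy)

    @property
    def kdtree(self) -> cKDTree:
        return self._tree


@dataclass
class ODMatrix:
    """Dense demand-point x facility cost matrix; unreachable pairs are +inf."""

    point_ids: list[str]
    facility_ids: list[str]
    time_min: np.ndarray  # (n_points, n_facilities)
    dist_km: np.ndarray  # network distance along the time-optimal path

    def __post_init__(self) -> None:
        expected = (len(self.point_ids), len(self.facility_ids))
        if self.time_min.shape != expected or self.dist_km.shape != expected:
            raise ValueError("OD matrix shape mismatch")
        finite = np.isfinite(self.time_min)
        if np.any(self.time_min[finite] < 0) or np.any(self.dist_km[np.isfinite(self.dist_km)] < 0):
            raise ValueError("negative OD costs")

    def facility_index(self, facility_id: str) -> int:
        return self.facility_ids.index(facility_id)

    def to_frame(self):
        """Long-form table ``point_id,facility_id,minutes,km`` (inf = unreachable)."""
        import pandas as pd

        rows = []
        for i, pid in enumerate(self.point_ids):
            for j, fid in enumerate(self.facility_ids):
                rows.append((pid, fid, self.time_min[i, j], self.dist_km[i, j]))
        return pd.DataFrame(rows, columns=["point_id", "facility_id", "minutes", "km"])


def edge_travel_time_min(length_m: float, speed_kmh: float) -> float:
    """Travel time in minutes for a segment of ``length_m`` at ``speed_kmh``."""
    return (length_m / 1000.0) / speed_kmh * 60.0


def build_graph(roads: RoadLayer, speeds: SpeedTable | None = None) -> TravelNetwork:
    """Build the travel network: one node per distinct polyline vertex, one
    edge per consecutive vertex pair, weighted by length and travel time.

    Zero-length segments (all vertices coincident) are dropped with a warning.
    When parallel edges connect the same node pair the faster one is kept.
    """
    speeds = speeds or SpeedTable()
    g = nx.Graph()
    node_index: dict[tuple[float, float], int] = {}
    coords_list: list[tuple[float, float]] = []
    dropped = 0

    def node_of(x: float, y: float) -> int:
        key = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS))
        idx = node_index.get(key)
        if idx is None:
            idx = len(coords_list)
            node_index[key] = idx
            coords_list.append(key)
            g.add_node(idx)
        return idx

    for seg in roads.segments:
        coords = list(seg.geometry.coords)
        speed = speeds[seg.road_class]
        any_edge = False
        for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
            length = math.hypot(x1 - x0, y1 - y0)
            if length <= 0:
                continue
            u, v = node_of(x0, y0), node_of(x1, y1)
            t = edge_travel_time_min(length, speed)
            if g.has_edge(u, v) and g[u][v]["time_min"] <= t:
                continue
            g.add_edge(u, v, length_m=length, time_min=t, road_class=seg.road_class,
                       segment_id=seg.segment_id)
            any_edge = True
        if not any_edge:
            dropped += 1
    if dropped:
        logger.warning("dropped %d zero-length road segments", dropped)
    if g.number_of_edges() == 0:
        raise ValueError("road layer produced an empty graph")
    return TravelNetwork(graph=g, node_xy=np.asarray(coords_list, dtype=float))


@dataclass
class SnapResult:
    """Node assignment of external points to the travel network."""

    node_ids: np.ndarray  # -1 where beyond max_snap_m
    snap_dist_m: np.ndarray

    @property
    def reachable(self) -> np.ndarray:
        return self.node_ids >= 0


def snap_points(
    xy: np.ndarray, network: TravelNetwork, max_snap_m: float = DEFAULT_MAX_SNAP_M
) -> SnapResult:
    """Assign each point to its nearest graph node by planar distance.

    Exact distance ties break to the lower node id; points farther than
    ``max_snap_m`` from any node are flagged unreachable (node id -1).
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if network.n_nodes == 0:
        raise ValueError("cannot snap to an empty network")
    k = min(4, network.n_nodes)
    dists, idxs = network.kdtree.query(xy, k=k)
    if k == 1:
        dists, idxs = dists[:, None], idxs[:, None]
    node_ids = np.empty(len(xy), dtype=int)
    best = np.empty(len(xy), dtype=float)
    for i in range(len(xy)):
        d0 = dists[i, 0]
        tied = idxs[i, np.abs(dists[i] - d0) <= 1e-9]
        node_ids[i] = int(tied.min())
        best[i] = d0
    too_far = best > max_snap_m
    node_ids[too_far] = -1
    if too_far.any():
        logger.warning("%d points beyond max_snap_m=%.0f flagged unreachable",
                       too_far.sum(), max_snap_m)
    return SnapResult(node_ids=node_ids, snap_dist_m=best)


def _single_source_costs(g: nx.Graph, source: int) -> tuple[dict, dict]:
    """Time-optimal costs from ``source``: minutes and km along the same path."""
    preds, time_min = nx.dijkstra_predecessor_and_distance(g, source, weight="time_min")
    dist_m: dict[int, float] = {source: 0.0}
    for node in sorted(time_min, key=time_min.get):
        if node == source:
            continue
        p = preds[node][0]
        dist_m[node] = dist_m[p] + g[p][node]["length_m"]
    return time_min, dist_m


def od_cost_matrix(
    network: TravelNetwork,
    demand_nodes: np.ndarray,
    facility_nodes: np.ndarray,
    point_ids: list[str],
    facility_ids: list[str],
) -> ODMatrix:
    """Shortest travel-time cost from every demand node to every facility node.

    Run from the (few) facility nodes; the network is undirected so facility->
    demand costs equal demand->facility. Unsnapped entries (node id -1) and
    disconnected pairs come back as +inf.
    """
    n, m = len(demand_nodes), len(facility_nodes)
    time_min = np.full((n, m), np.inf)
    dist_km = np.full((n, m), np.inf)
    cache: dict[int, tuple[dict, dict]] = {}
    for j, fnode in enumerate(facility_nodes):
        if fnode < 0:
            continue
        if fnode not in cache:
            cache[fnode] = _single_source_costs(network.graph, int(fnode))
        times, dists = cache[fnode]
        for i, dnode in enumerate(demand_nodes):
            if dnode < 0:
                continue
            t = times.get(int(dnode))
            if t is not None:
                time_min[i, j] = t
                dist_km[i, j] = dists[int(dnode)] / 1000.0
    return ODMatrix(point_ids=list(point_ids), facility_ids=list(facility_ids),
                    time_min=time_min, dist_km=dist_km)


def nearest_facility(
    od: ODMatrix, facility_subset: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per demand point, the minimum-time facility within ``facility_subset``.

    Returns (facility id array of dtype object, minutes array); unreachable
    points get (None, inf). Ties break to the lower facility id.
    """
    subset = list(od.facility_ids) if facility_subset is None else list(facility_subset)
    if not subset:
        raise ValueError("facility subset is empty")
    missing = set(subset) - set(od.facility_ids)
    if missing:
        raise ValueError(f"facilities not in OD matrix: {sorted(missing)}")
    # order columns by facility id so argmin's first-hit rule is the tie-break
    subset = sorted(subset)
    cols = [od.facility_ids.index(f) for f in subset]
    sub = od.time_min[:, cols]
    j_best = np.argmin(sub, axis=1)
    minutes = sub[np.arange(len(sub)), j_best]
    ids = np.array([subset[j] for j in j_best], dtype=object)
    ids[~np.isfinite(minutes)] = None
    return ids, minutes
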