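"""Road network model and its linear tessellation.

The linear tessellation is the analysis space for every network statistic in
this package: each road edge is split into short *basic linear units* that
play the role raster cells play in planar analysis.  Units carry a linear
reference (start/end measure along their parent edge), a traversal time, and
a symmetric adjacency relation; network algorithms (step-limited kernel
density expansion, step distances) operate on the unit adjacency graph.

Two tessellation modes are supported:

``equal_length``
    every edge is cut into units of (at most) a fixed defined length ``l_e``.

``isochronous``
    the target unit length on an edge is the edge's mode speed ``v_i`` (m/s),
    so traversing one unit takes one second; edges with no observed speed
    fall back to a configured minimum speed ``v_min``.

Edges whose length is not an exact multiple of the target are divided into
``ceil(length / target)`` units of equal length, keeping units homogeneous
per edge at the price of traversal times slightly below one second.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely import STRtree
from shapely.geometry import LineString, Point
from shapely.ops import substring

__all__ = [
    "Edge",
    "RoadNetwork",
    "TessellationConfig",
    "BasicLinearUnit",
    "LinearTessellation",
    "build_network",
    "tessellate",
]

#: relative tolerance for length bookkeeping invariants
LENGTH_RTOL = 1e-6


@dataclass(frozen=True)
class Edge:
    """A road segment between two network nodes.

    ``speeds`` maps transport-mode labels (``walk``, ``bicycle``, ``taxi``,
    ``metro``, ...) to mean speeds in m/s; modes without an observed speed are
    simply absent.
    """

    id: int
    u: int
    v: int
    geometry: LineString
    length: float
    speeds: Mapping[str, float] = field(default_factory=dict)

    def speed(self, mode: str) -> float:
        """Observed mean speed for *mode*, or 0.0 when unobserved."""
        return float(self.speeds.get(mode, 0.0))


class RoadNetwork:
    """An undirected planar road network in projected metric coordinates."""

    def __init__(self, nodes: dict[int, tuple[float, float]], edges: dict[int, Edge]):
        for e in edges.values():
            if e.u not in nodes or e.v not in nodes:
                raise ValueError(f"edge {e.id} references unregistered node")
            if e.length <= 0:
                raise ValueError(f"edge {e.id} has non-positive length")
            if abs(e.geometry.length - e.length) > LENGTH_RTOL * e.length:
                raise ValueError(f"edge {e.id} length disagrees with its geometry")
            if any(s < 0 for s in e.speeds.values()):
                raise ValueError(f"edge {e.id} has a negative speed entry")
        self.nodes = nodes
        self.edges = edges
        self._graph: nx.Graph | None = None
        self._edge_tree: STRtree | None = None
        self._edge_tree_ids: list[int] | None = None

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def total_length(self) -> float:
        return sum(e.length for e in self.edges.values())

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        xs = [p[0] for p in self.nodes.values()]
        ys = [p[1] for p in self.nodes.values()]
        return min(xs), min(ys), max(xs), max(ys)

    def graph(self) -> nx.Graph:
        """The node graph, edge weights = metric lengths (cached)."""
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for e in self.edges.values():
                # parallel edges: keep the shorter one for routing purposes
                if g.has_edge(e.u, e.v) and g[e.u][e.v]["weight"] <= e.length:
                    continue
                g.add_edge(e.u, e.v, weight=e.length, edge_id=e.id)
            self._graph = g
        return self._graph

    def nearest_edge(self, point: Point, max_dist: float | None = None) -> int | None:
        """Id of the edge nearest to *point* (ties → smallest id).

        Returns None when the nearest edge is farther than *max_dist*.
        """
        if self._edge_tree is None:
            self._edge_tree_ids = sorted(self.edges)
            self._edge_tree = STRtree(
                [self.edges[i].geometry for i in self._edge_tree_ids]
            )
        idx = self._edge_tree.nearest(point)
        d0 = point.distance(self.edges[self._edge_tree_ids[idx]].geometry)
        if max_dist is not None and d0 > max_dist:
            return None
        hits = self._edge_tree.query(point.buffer(d0 + 1e-9))
        best = min(
            self._edge_tree_ids[i]
            for i in hits
            if point.distance(self.edges[self._edge_tree_ids[i]].geometry) <= d0 + 1e-9
        )
        return best


def build_network(
    line_features: Iterable[tuple[Sequence[tuple[float, float]] | LineString, Mapping[str, float]]],
    snap_tolerance: float = 0.01,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from polylines with per-mode speeds.

    Parameters
    ----------
    line_features
        Iterable of ``(geometry, speeds)`` pairs; *geometry* is a coordinate
        sequence or LineString in projected metric coordinates, *speeds* maps
        mode labels to m/s.
    snap_tolerance
        Endpoints closer than this (m) are merged into a single node.
    """
    feats = []
    for i, (geom, speeds) in enumerate(line_features):
        ls = geom if isinstance(geom, LineString) else LineString(list(geom))
        if ls.length <= 0:
            raise ValueError(f"edge {i} has zero length")
        feats.append((ls, dict(speeds)))
    if not feats:
        return RoadNetwork({}, {})

    xs = [x for ls, _ in feats for x in ls.bounds[::2]]
    ys = [y for ls, _ in feats for y in ls.bounds[1::2]]
    span = max(max(xs) - min(xs), max(ys) - min(ys))
    if max(map(abs, xs)) <= 180 and max(map(abs, ys)) <= 90 and span <= 1.0:
        warnings.warn(
            "coordinate bounding box is consistent with lon/lat degrees; "
            "inputs must be in a projected metric system",
            stacklevel=2,
        )

    # grid-hash endpoint merging: quantize to the snap tolerance and look in
    # the 3x3 cell neighbourhood for an existing node
    nodes: dict[int, tuple[float, float]] = {}
    cell_index: dict[tuple[int, int], list[int]] = {}

    def node_for(pt: tuple[float, float]) -> int:
        cx, cy = int(math.floor(pt[0] / snap_tolerance)), int(
            math.floor(pt[1] / snap_tolerance)
        )
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for nid in cell_index.get((cx + dx, cy + dy), ()):
                    q = nodes[nid]
                    if math.hypot(q[0] - pt[0], q[1] - pt[1]) <= snap_tolerance:
                        return nid
        nid = len(nodes)
        nodes[nid] = pt
        cell_index.setdefault((cx, cy), []).append(nid)
        return nid

    edges: dict[int, Edge] = {}
    for eid, (ls, speeds) in enumerate(feats):
        coords = list(ls.coords)
        u = node_for(coords[0])
        v = node_for(coords[-1])
        edges[eid] = Edge(eid, u, v, ls, ls.length, speeds)
    return RoadNetwork(nodes, edges)


@dataclass(frozen=True)
class TessellationConfig:
    """Parameters of the linear tessellation.

    ``defined_length`` is the planar-raster analogue of cell size (default
    100 m); ``min_speed`` is the fallback speed for edges with no observation
    (default 0.8 m/s, a typical walking pace).
    """

    defined_length: float = 100.0
    min_speed: float = 0.8
    mode: str = "equal_length"
    transport_mode: str = "walk"

    def __post_init__(self) -> None:
        if self.defined_length <= 0:
            raise ValueError("defined_length must be > 0")
        if self.min_speed <= 0:
            raise ValueError("min_speed must be > 0")
        if self.mode not in ("equal_length", "isochronous"):
            raise ValueError(f"unknown tessellation mode {self.mode!r}")


@dataclass(frozen=True)
class BasicLinearUnit:
    """One linear unit of the tessellation, linearly referenced on its edge."""

    id: int
    edge_id: int
    start: float
    end: float
    length: float
    traversal_time: float
    center: tuple[float, float]
    geometry: LineString


class LinearTessellation:
    """The tessellated network: units, adjacency, and a spatial index."""

    def __init__(
        self,
        units: dict[int, BasicLinearUnit],
        adjacency: dict[int, set[int]],
        network: RoadNetwork,
        config: TessellationConfig,
    ):
        self.units = units
        self.adjacency = adjacency
        self.network = network
        self.config = config
        self._ids = sorted(units)
        self._tree = STRtree([units[i].geometry for i in self._ids]) if units else None

    def __len__(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[int]:
        return list(self._ids)

    @property
    def total_length(self) -> float:
        return sum(u.length for u in self.units.values())

    def lengths(self) -> np.ndarray:
        """Unit lengths in unit-id order."""
        return np.array([self.units[i].length for i in self._ids])

    def neighbours(self, unit_id: int) -> set[int]:
        """Adjacent unit ids (edge-mates plus units sharing a network node)."""
        if unit_id not in self.adjacency:
            raise KeyError(f"unknown unit id {unit_id}")
        return set(self.adjacency[unit_id])

    def snap_point(
        self, point: Point | tuple[float, float], max_snap_dist: float | None = None
    ) -> int | None:
        """Unit nearest to *point* in Euclidean distance (ties → smallest id).

        Returns None when the point is farther than *max_snap_dist* from
        every unit (unlimited by default).
        """
        if not self.units:
            raise ValueError("tessellation is empty")
        pt = point if isinstance(point, Point) else Point(point)
        idx = self._tree.nearest(pt)
        d0 = pt.distance(self.units[self._ids[idx]].geometry)
        if max_snap_dist is not None and d0 > max_snap_dist:
            return None
        hits = self._tree.query(pt.buffer(d0 + 1e-9))
        return min(
            self._ids[i]
            for i in hits
            if pt.distance(self.units[self._ids[i]].geometry) <= d0 + 1e-9
        )

    def snap_points(
        self,
        points: Iterable[Point | tuple[float, float]],
        max_snap_dist: float | None = None,
    ) -> list[int | None]:
        return [self.snap_point(p, max_snap_dist) for p in points]


def tessellate(network: RoadNetwork, config: TessellationConfig) -> LinearTessellation:
    """Split every edge of *network* into basic linear units.

    In ``equal_length`` mode the target unit length is ``defined_length``; in
    ``isochronous`` mode it is the edge's mode speed (numerically, L_i =
    l_e · v_i / l_e = v_i metres, a one-second unit), with ``min_speed``
    substituted where the speed is unobserved or zero.  Each edge is divided
    into ``ceil(length / target)`` units of equal length.
    """
    if len(network) == 0:
        raise ValueError("cannot tessellate an empty network")

    units: dict[int, BasicLinearUnit] = {}
    adjacency: dict[int, set[int]] = {}
    # per node: unit ids whose geometry touches the node
    node_units: dict[int, list[int]] = {n: [] for n in network.nodes}

    uid = 0
    for eid in sorted(network.edges):
        edge = network.edges[eid]
        if config.mode == "equal_length":
            target = config.defined_length
            v_eff = edge.speed(config.transport_mode) or config.min_speed
        else:
            v_i = edge.speed(config.transport_mode)
            v_eff = v_i if v_i > 0 else config.min_speed
            target = v_eff
        n = max(1, math.ceil(edge.length / target - 1e-12))
        step = edge.length / n
        first = uid
        for k in range(n):
            start, end = k * step, (k + 1) * step if k < n - 1 else edge.length
            geom = substring(edge.geometry, start, end)
            mid = edge.geometry.interpolate((start + end) / 2.0)
            units[uid] = BasicLinearUnit(
                id=uid,
                edge_id=eid,
                start=start,
                end=end,
                length=end - start,
                traversal_time=(end - start) / v_eff,
                center=(mid.x, mid.y),
                geometry=geom,
            )
            adjacency[uid] = set()
            if k > 0:
                adjacency[uid].add(uid - 1)
                adjacency[uid - 1].add(uid)
            uid += 1
        node_units[edge.u].append(first)
        node_units[edge.v].append(uid - 1)

    # all units meeting at a shared network node are pairwise adjacent
    for incident in node_units.values():
        for i, a in enumerate(incident):
            for b in incident[i + 1 :]:
                if a != b:
                    adjacency[a].add(b)
                    adjacency[b].add(a)

    return LinearTessellation(units, adjacency, network, config)
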