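"""Seeded synthetic-city generators.

These produce every input class the analyses consume — a lattice street
network, per-edge mode speeds, amenity point patterns (uniform or Thomas-
clustered *along the network*), noisy GPS trajectories of roughly constant
speed, and a center-decaying house-price field — so the full pipeline can
run and be tested without any external data.  Every generator is
deterministic under its seed.

The default city is a 10×10 lattice with 100 m spacing (~1 km across) with
mode speeds at the four travel-mode averages (walk 0.8, bicycle 3.6,
taxi 4.3, metro 1.1 m/s), a Thomas-clustered amenity process, and a house
price field decaying exponentially from the center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kfunction import PointPattern
from .network import Edge, RoadNetwork
from .speeds import EdgeSpeedTable, TrajectoryPoint

__all__ = [
    "SyntheticCityConfig",
    "SyntheticCity",
    "gen_grid_network",
    "gen_edge_speeds",
    "gen_amenities",
    "gen_trajectories",
    "gen_price_field",
    "gen_city",
]

MODE_SPEEDS = {"walk": 0.8, "bicycle": 3.6, "taxi": 4.3, "metro": 1.1}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_grid_network(
    rows: int, cols: int, spacing: float = 100.0, seed=None, jitter: float = 0.0
) -> RoadNetwork:
    """A rows×cols lattice street network with optional node jitter.

    Produces rows·cols nodes and 2·rows·cols − rows − cols edges.
    """
    if rows < 2 or cols < 2:
        raise ValueError("need at least a 2×2 lattice")
    rng = _rng(seed)
    nodes: dict[int, tuple[float, float]] = {}
    for r in range(rows):
        for c in range(cols):
            x, y = c * spacing, r * spacing
            if jitter > 0:
                x += rng.normal(0, jitter)
                y += rng.normal(0, jitter)
            nodes[r * cols + c] = (x, y)
    from shapely.geometry import LineString

    edges: dict[int, Edge] = {}
    eid = 0
    for r in range(rows):
        for c in range(cols):
            nid = r * cols + c
            if c + 1 < cols:
                geom = LineString([nodes[nid], nodes[nid + 1]])
                edges[eid] = Edge(eid, nid, nid + 1, geom, geom.length, {})
                eid += 1
            if r + 1 < rows:
                geom = LineString([nodes[nid], nodes[nid + cols]])
                edges[eid] = Edge(eid, nid, nid + cols, geom, geom.length, {})
                eid += 1
    return RoadNetwork(nodes, edges)


def gen_edge_speeds(
    network: RoadNetwork, mode: str, mean: float, sd: float = 0.0, seed=None
) -> EdgeSpeedTable:
    """Per-edge speeds ~ Normal(mean, sd), truncated just above zero."""
    if mean <= 0:
        raise ValueError("mean speed must be > 0")
    rng = _rng(seed)
    speeds = {}
    for eid in sorted(network.edges):
        v = rng.normal(mean, sd) if sd > 0 else mean
        speeds[(eid, mode)] = max(v, 0.05 * mean)
    return EdgeSpeedTable(speeds=speeds, counts={k: 0 for k in speeds})


def _walk_from(
    network: RoadNetwork,
    eid: int,
    measure: float,
    distance: float,
    rng: np.random.Generator,
) -> tuple[int, float]:
    """Move *distance* along the network from (edge, measure), choosing a
    uniformly random incident edge at each node; returns the final position."""
    g = network.graph()
    edge = network.edges[eid]
    direction = 1 if rng.random() < 0.5 else -1
    pos = measure
    while distance > 0:
        room = (edge.length - pos) if direction > 0 else pos
        if distance <= room:
            pos += direction * distance
            return edge.id, pos
        distance -= room
        node = edge.v if direction > 0 else edge.u
        incident = sorted(
            data["edge_id"] for _, _, data in g.edges(node, data=True)
        )
        nxt = network.edges[incident[rng.integers(len(incident))]]
        edge = nxt
        direction = 1 if nxt.u == node else -1
        pos = 0.0 if direction > 0 else nxt.length
    return edge.id, pos


def gen_amenities(
    network: RoadNetwork,
    process: str,
    n: int,
    seed=None,
    n_parents: int = 8,
    cluster_radius: float = 150.0,
    parent_region: tuple[float, float, float, float] | None = None,
) -> PointPattern:
    """Amenity points on the network.

    ``uniform``: i.i.d. uniform by length (the CSR process).  ``thomas``:
    parents uniform by length (optionally restricted to *parent_region*),
    offspring displaced from their parent *along network paths* within
    ``cluster_radius``, so the clustering is meaningful in network space.
    """
    from .kfunction import random_pattern

    rng = _rng(seed)
    if n == 0:
        return PointPattern(np.empty((0, 2)), np.empty(0, int), np.empty(0))
    if process == "uniform":
        return random_pattern(network, n, rng)
    if process != "thomas":
        raise ValueError(f"unknown amenity process {process!r}")

    def draw_on_network(k: int) -> PointPattern:
        return random_pattern(network, k, rng)

    # rejection-sample parents into the requested region
    parents: list[tuple[int, float]] = []
    while len(parents) < n_parents:
        pat = draw_on_network(n_parents)
        for i in range(pat.n):
            if len(parents) >= n_parents:
                break
            x, y = pat.xy[i]
            if parent_region is not None:
                x0, y0, x1, y1 = parent_region
                if not (x0 <= x <= x1 and y0 <= y <= y1):
                    continue
            parents.append((int(pat.edge_ids[i]), float(pat.measures[i])))

    edge_ids = np.empty(n, dtype=int)
    measures = np.empty(n)
    for i in range(n):
        peid, pm = parents[rng.integers(len(parents))]
        d = rng.uniform(0.0, cluster_radius)
        edge_ids[i], measures[i] = _walk_from(network, peid, pm, d, rng)
    return PointPattern.from_network(network, edge_ids, measures)


def gen_trajectories(
    network: RoadNetwork,
    mode: str,
    true_speed: float,
    n_traces: int,
    noise_sd: float = 2.0,
    fix_dt: float = 10.0,
    duration: float = 600.0,
    seed=None,
) -> list[list[TrajectoryPoint]]:
    """GPS traces: random walks along edges at *true_speed* with isotropic
    Gaussian position noise and fixes every *fix_dt* seconds."""
    if true_speed <= 0:
        raise ValueError("true_speed must be > 0")
    rng = _rng(seed)
    from .kfunction import random_pattern

    traces = []
    n_fix = int(duration // fix_dt) + 1
    for k in range(n_traces):
        start = random_pattern(network, 1, rng)
        eid, m = int(start.edge_ids[0]), float(start.measures[0])
        pts = []
        for j in range(n_fix):
            edge = network.edges[eid]
            p = edge.geometry.interpolate(m)
            x = p.x + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            y = p.y + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            pts.append(TrajectoryPoint(f"trace{k}", mode, j * fix_dt, x, y))
            eid, m = _walk_from(network, eid, m, true_speed * fix_dt, rng)
        traces.append(pts)
    return traces


def gen_price_field(
    bounds: tuple[float, float, float, float],
    center: tuple[float, float],
    center_price: float = 50000.0,
    decay_len: float = 300.0,
    noise_sd: float = 1000.0,
    n: int = 500,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """House-price points: center_price·exp(−dist/decay_len) + noise, ≥ 0."""
    if center_price <= 0:
        raise ValueError("center_price must be > 0")
    rng = _rng(seed)
    x0, y0, x1, y1 = bounds
    xy = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    dist = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])
    prices = center_price * np.exp(-dist / decay_len)
    if noise_sd > 0:
        prices = prices + rng.normal(0, noise_sd, size=n)
    return xy, np.maximum(prices, 0.0)


@dataclass(frozen=True)
class SyntheticCityConfig:
    """The study conditions of the synthetic city (all draws fixed by seed)."""

    rows: int = 10
    cols: int = 10
    spacing: float = 100.0
    mode_speeds: dict = field(default_factory=lambda: dict(MODE_SPEEDS))
    speed_dispersion: float = 0.1  # sd as fraction of the mean
    amenity_process: str = "thomas"
    n_amenities: int = 60
    n_parents: int = 8
    cluster_radius: float = 150.0
    center_rich: bool = True  # parents restricted to the central third
    center_price: float = 50000.0
    price_decay_len: float = 300.0
    price_noise_sd: float = 1000.0
    n_price_points: int = 500
    n_traces: int = 30
    gps_noise_sd: float = 2.0
    fix_dt: float = 10.0
    trace_duration: float = 600.0
    seed: int = 0


@dataclass
class SyntheticCity:
    config: SyntheticCityConfig
    network: RoadNetwork  # carries per-mode edge speeds
    amenities: PointPattern
    trajectories: dict[str, list[list[TrajectoryPoint]]]
    price_xy: np.ndarray
    price_values: np.ndarray

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.network.bounds
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def gen_city(config: SyntheticCityConfig = SyntheticCityConfig()) -> SyntheticCity:
    """Generate the full synthetic city bundle from one seed."""
    rng = np.random.default_rng(config.seed)
    net = gen_grid_network(config.rows, config.cols, config.spacing, seed=rng)
    for mode, mean in config.mode_speeds.items():
        table = gen_edge_speeds(
            net, mode, mean, config.speed_dispersion * mean, seed=rng
        )
        net = table.apply(net)

    x0, y0, x1, y1 = net.bounds
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    region = None
    if config.center_rich:
        sx, sy = (x1 - x0) / 6.0, (y1 - y0) / 6.0
        region = (cx - sx, cy - sy, cx + sx, cy + sy)
    amenities = gen_amenities(
        net,
        config.amenity_process,
        config.n_amenities,
        seed=rng,
        n_parents=config.n_parents,
        cluster_radius=config.cluster_radius,
        parent_region=region,
    )

    trajectories = {
        mode: gen_trajectories(
            net,
            mode,
            config.mode_speeds[mode],
            config.n_traces,
            config.gps_noise_sd,
            config.fix_dt,
            config.trace_duration,
            seed=rng,
        )
        for mode in config.mode_speeds
    }

    price_xy, price_values = gen_price_field(
        net.bounds,
        (cx, cy),
        config.center_price,
        config.price_decay_len,
        config.price_noise_sd,
        config.n_price_points,
        seed=rng,
    )
    return SyntheticCity(config, net, amenities, trajectories, price_xy, price_values)
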