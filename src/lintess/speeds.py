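"""Per-edge, per-mode speed estimation from GPS trajectories.

Raw interval speeds (distance between consecutive fixes over elapsed time)
are smoothed with a one-dimensional Kalman filter whose state is the true
speed, modelled as a random walk; each smoothed interval is then assigned to
the road edge nearest its midpoint and edge speeds are the per-edge means.
Edges no trace covers are simply absent from the table — downstream, the
isochronous tessellation treats them as unobserved and falls back to the
configured minimum speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .network import RoadNetwork

__all__ = [
    "TrajectoryPoint",
    "EdgeSpeedTable",
    "raw_speeds",
    "kalman_smooth",
    "estimate_edge_speeds",
    "set_constant_mode_speed",
]


@dataclass(frozen=True)
class TrajectoryPoint:
    trace_id: str
    mode: str
    t: float
    x: float
    y: float


@dataclass
class EdgeSpeedTable:
    """(edge id, mode) → mean speed (m/s) and supporting interval count."""

    speeds: dict[tuple[int, str], float] = field(default_factory=dict)
    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def get(self, edge_id: int, mode: str) -> float | None:
        return self.speeds.get((edge_id, mode))

    def apply(self, network: RoadNetwork) -> RoadNetwork:
        """Return a network whose edges carry these speeds."""
        from .network import Edge

        edges = {}
        for eid, e in network.edges.items():
            sp = dict(e.speeds)
            for (eid2, mode), v in self.speeds.items():
                if eid2 == eid:
                    sp[mode] = v
            edges[eid] = Edge(e.id, e.u, e.v, e.geometry, e.length, sp)
        return RoadNetwork(dict(network.nodes), edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"edge_id": eid, "mode": mode, "speed_mps": v,
             "n_points": self.counts.get((eid, mode), 0)}
            for (eid, mode), v in sorted(self.speeds.items())
        ]
        return pd.DataFrame(rows, columns=["edge_id", "mode", "speed_mps", "n_points"])


def raw_speeds(trace: list[TrajectoryPoint]) -> np.ndarray:
    """Euclidean speed of each inter-fix interval, m/s."""
    if len(trace) < 2:
        raise ValueError("a trace needs at least 2 points")
    t = np.array([p.t for p in trace], dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(
            f"non-increasing timestamps in trace {trace[0].trace_id!r}"
        )
    xy = np.array([(p.x, p.y) for p in trace], dtype=float)
    dist = np.hypot(*np.diff(xy, axis=0).T)
    return dist / dt


def kalman_smooth(
    speeds: np.ndarray, process_var: float = 0.1, meas_var: float = 1.0
) -> np.ndarray:
    """Kalman-filter a speed sequence under a random-walk state model.

    State: true speed, transition identity + N(0, process_var); observation:
    raw speed + N(0, meas_var).  The filter is initialised on the first
    observation.  As ``meas_var → 0`` the output converges to the input.
    """
    speeds = np.asarray(speeds, dtype=float)
    if not np.all(np.isfinite(speeds)):
        raise ValueError("speeds must be finite")
    if process_var <= 0 or meas_var <= 0:
        raise ValueError("variances must be > 0")
    out = np.empty_like(speeds)
    x, p = speeds[0], meas_var
    out[0] = x
    for j in range(1, len(speeds)):
        p = p + process_var
        k = p / (p + meas_var)
        x = x + k * (speeds[j] - x)
        p = (1.0 - k) * p
        out[j] = x
    return out


def estimate_edge_speeds(
    network: RoadNetwork,
    traces: list[list[TrajectoryPoint]],
    mode: str,
    max_snap_dist: float | None = 50.0,
    process_var: float = 0.1,
    meas_var: float = 1.0,
) -> EdgeSpeedTable:
    """Mean smoothed speed per edge from traces of one transport mode.

    Interval midpoints are matched to the nearest edge within
    *max_snap_dist* (m); unmatched intervals are dropped.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for trace in traces:
        pts = [p for p in trace if p.mode == mode]
        if len(pts) < 2:
            continue
        v = kalman_smooth(raw_speeds(pts), process_var, meas_var)
        for j in range(len(pts) - 1):
            mid = Point(
                (pts[j].x + pts[j + 1].x) / 2.0, (pts[j].y + pts[j + 1].y) / 2.0
            )
            eid = network.nearest_edge(mid, max_dist=max_snap_dist)
            if eid is None:
                continue
            sums[eid] = sums.get(eid, 0.0) + float(v[j])
            counts[eid] = counts.get(eid, 0) + 1
    table = EdgeSpeedTable(
        speeds={(eid, mode): sums[eid] / counts[eid] for eid in sums},
        counts={(eid, mode): counts[eid] for eid in counts},
    )
    if not table.speeds:
        warnings.warn(f"no trace covered any edge for mode {mode!r}", stacklevel=2)
    return table


def set_constant_mode_speed(
    network: RoadNetwork, mode: str, speed: float
) -> EdgeSpeedTable:
    """Assign one constant speed to every edge for *mode*.

    Used for scheduled modes (e.g. metro, whose speed comes from line length
    over operation time rather than from trajectories).
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    return EdgeSpeedTable(
        speeds={(eid, mode): float(speed) for eid in network.edges},
        counts={(eid, mode): 0 for eid in network.edges},
    )
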