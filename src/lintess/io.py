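"""Readers and writers for the package's file dialects.

GeoJSON FeatureCollections (projected metric coordinates) carry networks,
points and tessellation units; CSV carries trajectories, speed tables,
density fields, K-function curves and grids.  Every writer's output
re-reads into an equal in-memory object.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityField, PlanarGrid
from .kfunction import KFunctionResult, PointPattern
from .network import LinearTessellation, RoadNetwork, build_network
from .speeds import EdgeSpeedTable, TrajectoryPoint

__all__ = [
    "read_network",
    "write_network",
    "read_points",
    "write_points",
    "read_price_points",
    "write_price_points",
    "read_trajectories",
    "write_trajectories",
    "write_tessellation",
    "write_speed_table",
    "read_speed_table",
    "write_density",
    "write_k_result",
    "write_grid",
]

SPEED_KEYS = ("walk", "bicycle", "taxi", "metro")


def _load_feature_collection(path: str | Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return doc.get("features", [])


def read_network(path: str | Path, snap_tolerance: float = 0.01) -> RoadNetwork:
    """Road network from a GeoJSON LineString collection with speed properties."""
    features = _load_feature_collection(path)
    if not features:
        warnings.warn(f"{path}: empty feature collection", stacklevel=2)
    line_features = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValueError(
                f"{path}: feature {i} has geometry {geom.get('type')!r}, "
                "expected LineString"
            )
        props = feat.get("properties") or {}
        speeds = {k: float(props[k]) for k in SPEED_KEYS if props.get(k) is not None}
        line_features.append(([tuple(c) for c in geom["coordinates"]], speeds))
    return build_network(line_features, snap_tolerance)


def write_network(network: RoadNetwork, path: str | Path) -> None:
    features = []
    for eid in sorted(network.edges):
        e = network.edges[eid]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(c) for c in e.geometry.coords],
                },
                "properties": {"edge_id": eid, **{k: v for k, v in e.speeds.items()}},
            }
        )
    _dump_fc(features, path)


def _dump_fc(features: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_points(path: str | Path) -> tuple[np.ndarray, list[dict]]:
    """Point coordinates and their property dicts from GeoJSON."""
    features = _load_feature_collection(path)
    if not features:
        warnings.warn(f"{path}: empty feature collection", stacklevel=2)
    xy, props = [], []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(
                f"{path}: feature {i} has geometry {geom.get('type')!r}, "
                "expected Point"
            )
        xy.append(tuple(geom["coordinates"][:2]))
        props.append(feat.get("properties") or {})
    return np.array(xy, dtype=float).reshape(-1, 2), props


def write_points(
    xy: np.ndarray, path: str | Path, properties: list[dict] | None = None
) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": (properties[i] if properties else {}),
        }
        for i, (x, y) in enumerate(np.asarray(xy).reshape(-1, 2))
    ]
    _dump_fc(features, path)


def read_price_points(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """House-price points; each feature must carry ``price_per_m2``."""
    xy, props = read_points(path)
    prices = []
    for i, p in enumerate(props):
        if "price_per_m2" not in p:
            raise ValueError(f"{path}: feature {i} missing 'price_per_m2'")
        prices.append(float(p["price_per_m2"]))
    return xy, np.array(prices)


def write_price_points(xy: np.ndarray, prices: np.ndarray, path: str | Path) -> None:
    write_points(xy, path, [{"price_per_m2": float(v)} for v in prices])


def read_trajectories(path: str | Path) -> list[list[TrajectoryPoint]]:
    """Traces from CSV (trace_id, mode, t_unix_s, x_m, y_m), grouped by trace."""
    df = pd.read_csv(path)
    required = {"trace_id", "mode", "t_unix_s", "x_m", "y_m"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("t_unix_s")
        traces.append(
            [
                TrajectoryPoint(str(tid), str(r.mode), float(r.t_unix_s),
                                float(r.x_m), float(r.y_m))
                for r in grp.itertuples()
            ]
        )
    return traces


def write_trajectories(traces: list[list[TrajectoryPoint]], path: str | Path) -> None:
    rows = [
        {"trace_id": p.trace_id, "mode": p.mode, "t_unix_s": p.t,
         "x_m": p.x, "y_m": p.y}
        for trace in traces
        for p in trace
    ]
    pd.DataFrame(rows, columns=["trace_id", "mode", "t_unix_s", "x_m", "y_m"]).to_csv(
        path, index=False
    )


def write_tessellation(
    tess: LinearTessellation, geojson_path: str | Path, adjacency_path: str | Path
) -> None:
    """Unit geometries with linear references (GeoJSON) + adjacency edge list (CSV)."""
    features = []
    for uid in tess.unit_ids:
        u = tess.units[uid]
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(c) for c in u.geometry.coords],
                },
                "properties": {
                    "unit_id": u.id,
                    "edge_id": u.edge_id,
                    "start_m": u.start,
                    "end_m": u.end,
                    "length_m": u.length,
                    "traversal_time_s": u.traversal_time,
                },
            }
        )
    _dump_fc(features, geojson_path)
    rows = [
        {"unit_a": a, "unit_b": b}
        for a in tess.unit_ids
        for b in sorted(tess.adjacency[a])
        if a < b
    ]
    pd.DataFrame(rows, columns=["unit_a", "unit_b"]).to_csv(adjacency_path, index=False)


def write_speed_table(table: EdgeSpeedTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_speed_table(path: str | Path) -> EdgeSpeedTable:
    df = pd.read_csv(path)
    return EdgeSpeedTable(
        speeds={(int(r.edge_id), str(r.mode)): float(r.speed_mps)
                for r in df.itertuples()},
        counts={(int(r.edge_id), str(r.mode)): int(r.n_points)
                for r in df.itertuples()},
    )


def write_density(field: DensityField, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": field.ids,
            "mode": field.transport_mode,
            "space": field.space,
            "kde_value": field.values,
        }
    ).to_csv(path, index=False)


def write_k_result(result: KFunctionResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_grid(grid: PlanarGrid, values: np.ndarray, path: str | Path,
               column: str = "value") -> None:
    """Grid cells as CSV rows (cell_id, row, col, x, y, value-or-label)."""
    centers = grid.cell_centers()
    cells = np.arange(grid.n_cells)
    pd.DataFrame(
        {
            "cell_id": cells,
            "row": cells // grid.n_cols,
            "col": cells % grid.n_cols,
            "x": centers[:, 0],
            "y": centers[:, 1],
            column: np.asarray(values).ravel(),
        }
    ).to_csv(path, index=False)
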