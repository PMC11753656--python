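"""The five-stage identification pipeline.

(1) build the isochronous linear tessellation from the road network and
per-mode speeds; (2) network KDE of the amenity points per mode; (3)
network K-function of the amenities with CSR envelopes; (4) income from
house prices via the price-to-income ratio, kriged to a grid; (5) overlay
of binarised accessibility and income into HH/HL/LH/LL risk patterns.

All intermediate artifacts are written to the output directory and a
summary report (scope per mode, K labels, pattern proportions) is returned
and written as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from shapely.geometry import Point

from . import io
from .config import RunConfig
from .density import DensityField, KDEConfig, PlanarGrid, accessibility_scope, network_kde, planar_kde
from .economics import (
    income_from_price,
    interpolate_to_grid,
    overlay_patterns,
    pattern_proportions,
    reclassify,
)
from .kfunction import (
    KFunctionConfig,
    PointPattern,
    default_h_grid,
    network_k_analysis,
)
from .network import RoadNetwork, TessellationConfig, tessellate
from .speeds import estimate_edge_speeds, set_constant_mode_speed
from .synth import MODE_SPEEDS, gen_city
from .thin import grid_thin

__all__ = ["run_pipeline", "pattern_from_xy"]

log = logging.getLogger("lintess")


def pattern_from_xy(network: RoadNetwork, xy: np.ndarray) -> PointPattern:
    """Snap free planar points onto the network (nearest edge + projection)."""
    edge_ids, measures = [], []
    for x, y in np.asarray(xy).reshape(-1, 2):
        p = Point(x, y)
        eid = network.nearest_edge(p)
        if eid is None:
            raise ValueError(f"point ({x}, {y}) lies on no edge")
        edge = network.edges[eid]
        measures.append(edge.geometry.project(p))
        edge_ids.append(eid)
    return PointPattern.from_network(network, np.array(edge_ids), np.array(measures))


def run_pipeline(config: RunConfig) -> dict:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "modes": {}}

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.synthetic is not None:
            city = gen_city(
                dataclasses.replace(config.synthetic, seed=config.seed)
            )
            network = city.network
            amen_xy = city.amenities.xy
            amen_pattern = city.amenities
            traces_by_mode = city.trajectories
            price_xy, price_values = city.price_xy, city.price_values
            io.write_network(network, out / "network.geojson")
            io.write_points(amen_xy, out / "amenities.geojson")
            io.write_price_points(price_xy, price_values, out / "prices.geojson")
        else:
            network = io.read_network(config.network_path)
            amen_xy, _ = io.read_points(config.amenities_path)
            amen_pattern = None
            traces = (
                io.read_trajectories(config.trajectories_path)
                if config.trajectories_path
                else []
            )
            traces_by_mode = {
                m: [t for t in traces if t and t[0].mode == m] for m in config.modes
            }
            price_xy, price_values = (
                io.read_price_points(config.prices_path)
                if config.prices_path
                else (None, None)
            )
        log.info("inputs: %d edges, %d amenities", len(network), len(amen_xy))

        # ---- stage 1+2: speeds, tessellation, network KDE per mode --------
        fields: dict[str, DensityField] = {}
        for mode in config.modes:
            stage = f"speeds[{mode}]"
            traces = traces_by_mode.get(mode, [])
            if mode == "metro":
                table = set_constant_mode_speed(network, mode, MODE_SPEEDS["metro"])
            elif traces:
                table = estimate_edge_speeds(network, traces, mode)
            else:
                table = None
            if table is not None and config.synthetic is None:
                network = table.apply(network)
            if table is not None:
                io.write_speed_table(table, out / f"speeds_{mode}.csv")

            stage = f"tessellate[{mode}]"
            tess = tessellate(
                network,
                TessellationConfig(
                    defined_length=config.defined_length,
                    min_speed=config.min_speed,
                    mode="isochronous",
                    transport_mode=mode,
                ),
            )
            io.write_tessellation(
                tess, out / f"units_{mode}.geojson", out / f"adjacency_{mode}.csv"
            )
            log.info("tessellate[%s]: %d units", mode, len(tess))

            stage = f"kde[{mode}]"
            tau = int(config.tau_steps[mode])
            field = network_kde(
                tess, [Point(p) for p in amen_xy], KDEConfig(tau, "network",
                                                             transport_mode=mode)
            )
            fields[mode] = field
            io.write_density(field, out / f"kde_network_{mode}.csv")
            scope = accessibility_scope(field)
            summary["modes"][mode] = {"tau_steps": tau, "scope_pct": scope}
            log.info("kde[%s]: tau=%d scope=%.1f%%", mode, tau, scope)

            if config.run_planar:
                grid = PlanarGrid.from_bounds(network.bounds, config.grid_cell_m)
                pfield = planar_kde(
                    grid,
                    [Point(p) for p in amen_xy],
                    KDEConfig(config.planar_bandwidths[mode], "planar",
                              transport_mode=mode),
                )
                io.write_density(pfield, out / f"kde_planar_{mode}.csv")
                summary["modes"][mode]["scope_planar_pct"] = accessibility_scope(pfield)

        # ---- stage 3: K-function ------------------------------------------
        stage = "kfunction"
        if amen_pattern is None:
            amen_pattern = pattern_from_xy(network, amen_xy)
        h_grid = default_h_grid(network, config.kfunction_n_h)
        kconf = KFunctionConfig(
            h_grid,
            n_sim=config.kfunction_n_sim,
            significance=config.kfunction_significance,
            seed=config.seed + 1,
        )
        kres = network_k_analysis(network, amen_pattern, kconf)
        io.write_k_result(kres, out / "kfunction_network.csv")
        summary["kfunction"] = {
            "labels": kres.labels,
            "n_points": amen_pattern.n,
            "n_sim": config.kfunction_n_sim,
        }
        log.info("kfunction: %d points, labels %s", amen_pattern.n,
                 sorted(set(kres.labels)))

        # ---- stage 4: income surface --------------------------------------
        grid = PlanarGrid.from_bounds(network.bounds, config.grid_cell_m)
        income_grid = None
        if price_xy is not None and len(price_xy) >= 10:
            stage = "income"
            incomes = income_from_price(price_values, config.income)
            income_grid = interpolate_to_grid(
                price_xy, incomes, grid,
                family=config.variogram_family, n_lags=config.variogram_n_lags,
            )
            io.write_grid(grid, income_grid, out / "income_grid.csv", "income")
            log.info("income: %d price points kriged to %d cells",
                     len(price_xy), grid.n_cells)

        # ---- stage 5: overlay ---------------------------------------------
        if income_grid is not None:
            income_bin = reclassify(income_grid, "income", config.income)
            for mode, field in fields.items():
                stage = f"overlay[{mode}]"
                tess = field.support
                centers = np.array([tess.units[int(i)].center for i in field.ids])
                thin_xy, thin_vals = grid_thin(centers, config.grid_cell_m,
                                               field.values)
                kde_grid = interpolate_to_grid(
                    thin_xy, thin_vals, grid,
                    family=config.variogram_family,
                    n_lags=config.variogram_n_lags,
                )
                access_bin = reclassify(kde_grid, "kde", config.income)
                pm = overlay_patterns(access_bin, income_bin, grid)
                pm.to_frame().to_csv(out / f"patterns_{mode}.csv", index=False)
                props = pattern_proportions(pm)
                summary["modes"][mode]["pattern_pct"] = props
                log.info("overlay[%s]: %s", mode,
                         {k: round(v, 1) for k, v in props.items()})
    except Exception as exc:  # annotate which stage failed, keep partial output
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
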