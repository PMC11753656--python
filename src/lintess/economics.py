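"""Income estimation from house prices and the accessibility/income overlay.

Per-capita disposable income is derived from house price per square meter
through the housing price-to-income ratio,

    I = P_h · A_h / R,

with housing area per capita A_h and ratio R taken from municipal
statistics (defaults 36.7 m² and 17.1; low-income threshold 27,600 per
year).  Point-supported income and network-KDE values are interpolated to a
common planar grid by ordinary kriging, binarised (KDE > 0; income strictly
above the threshold — income exactly at the threshold counts as low), and
cross-combined into four patterns with increasing food-desert risk:

    (1,1) → HH risk 0,  (1,0) → HL risk 1,  (0,1) → LH risk 2,
    (0,0) → LL risk 3 (the food-desert class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DensityField, PlanarGrid
from .kriging import VariogramModel, fit_variogram, ordinary_kriging

__all__ = [
    "IncomeConfig",
    "IncomeSurface",
    "PatternMap",
    "income_from_price",
    "interpolate_to_grid",
    "kde_field_to_grid",
    "reclassify",
    "overlay_patterns",
    "pattern_proportions",
    "PATTERNS",
]

#: (access_bin, income_bin) → (pattern label, risk level)
PATTERNS = {(1, 1): ("HH", 0), (1, 0): ("HL", 1), (0, 1): ("LH", 2), (0, 0): ("LL", 3)}


@dataclass(frozen=True)
class IncomeConfig:
    housing_per_capita: float = 36.7  # A_h, m² per person
    price_income_ratio: float = 17.1  # R
    low_income_threshold: float = 27600.0  # currency / year

    def __post_init__(self) -> None:
        if min(self.housing_per_capita, self.price_income_ratio,
               self.low_income_threshold) <= 0:
            raise ValueError("income parameters must be positive")


@dataclass
class IncomeSurface:
    """Gridded per-capita income."""

    grid: PlanarGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size != self.grid.n_cells:
            raise ValueError("value count must match the grid")
        if np.any(self.values < 0):
            raise ValueError("income values must be non-negative")


@dataclass
class PatternMap:
    """Per-cell HH/HL/LH/LL pattern labels and risk levels 0–3."""

    grid: PlanarGrid
    patterns: np.ndarray  # of str labels
    risk: np.ndarray  # int 0..3

    def to_frame(self) -> pd.DataFrame:
        centers = self.grid.cell_centers()
        cells = np.arange(self.grid.n_cells)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "row": cells // self.grid.n_cols,
                "col": cells % self.grid.n_cols,
                "x": centers[:, 0],
                "y": centers[:, 1],
                "pattern": self.patterns,
                "risk": self.risk,
            }
        )


def income_from_price(
    price_per_m2: float | np.ndarray, config: IncomeConfig = IncomeConfig()
) -> float | np.ndarray:
    """I = P_h · A_h / R (linear, order-preserving in price)."""
    price = np.asarray(price_per_m2, dtype=float)
    if np.any(price < 0):
        raise ValueError("price must be non-negative")
    income = price * config.housing_per_capita / config.price_income_ratio
    return float(income) if income.ndim == 0 else income


def interpolate_to_grid(
    xy: np.ndarray,
    values: np.ndarray,
    grid: PlanarGrid,
    variogram: VariogramModel | None = None,
    family: str = "spherical",
    n_lags: int = 12,
    clamp_zero: bool = True,
) -> np.ndarray:
    """Ordinary-kriging interpolation of point values onto grid cell centers.

    Kriging can undershoot below zero; densities and incomes are defined on
    [0, ∞), so negative predictions are clamped to 0 by default.
    """
    model = variogram or fit_variogram(xy, values, family=family, n_lags=n_lags)
    pred = ordinary_kriging(xy, values, grid.cell_centers(), model)
    return np.maximum(pred, 0.0) if clamp_zero else pred


def kde_field_to_grid(
    field: DensityField, grid: PlanarGrid, **kwargs
) -> np.ndarray:
    """Krige a network density field (supported on unit centers) to a grid."""
    if field.space != "network":
        raise ValueError("expected a network-space density field")
    tess = field.support
    xy = np.array([tess.units[int(i)].center for i in field.ids])
    return interpolate_to_grid(xy, field.values, grid, **kwargs)


def reclassify(
    values: np.ndarray, kind: str, config: IncomeConfig = IncomeConfig()
) -> np.ndarray:
    """Binarise a surface: kde → 1 iff value > 0; income → 1 iff value > threshold."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("surface values must be finite")
    if kind == "kde":
        return (values > 0).astype(int)
    if kind == "income":
        return (values > config.low_income_threshold).astype(int)
    raise ValueError(f"unknown surface kind {kind!r}")


def overlay_patterns(
    access_bin: np.ndarray, income_bin: np.ndarray, grid: PlanarGrid | None = None
) -> PatternMap:
    """Cross-combine binary accessibility and income grids into patterns."""
    access_bin = np.asarray(access_bin, dtype=int)
    income_bin = np.asarray(income_bin, dtype=int)
    if access_bin.shape != income_bin.shape:
        raise ValueError("grid shape mismatch between accessibility and income")
    flat_a, flat_i = access_bin.ravel(), income_bin.ravel()
    patterns = np.array([PATTERNS[(a, i)][0] for a, i in zip(flat_a, flat_i)])
    risk = np.array([PATTERNS[(a, i)][1] for a, i in zip(flat_a, flat_i)])
    if grid is None:
        n = flat_a.size
        grid = PlanarGrid((0.0, 0.0), 1.0, 1, n)
    return PatternMap(grid, patterns, risk)


def pattern_proportions(pattern_map: PatternMap) -> dict[str, float]:
    """Cell-count share of each pattern, in percent (sums to 100)."""
    if pattern_map.patterns.size == 0:
        raise ValueError("empty pattern map")
    total = pattern_map.patterns.size
    return {
        label: 100.0 * float(np.sum(pattern_map.patterns == label)) / total
        for label, _ in PATTERNS.values()
    }
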