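"""Variogram fitting and ordinary kriging on numpy/scipy.

Semivariogram families use the *practical range* convention: ``range_`` is
the lag at which the model reaches ~95% of the sill (exactly the sill for
the spherical family).  Ordinary kriging solves the standard semivariance
system with a Lagrange multiplier, so weights sum to one per prediction and
the predictor is exact at sample locations when the nugget is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = ["VariogramModel", "empirical_variogram", "fit_variogram", "ordinary_kriging"]


@dataclass(frozen=True)
class VariogramModel:
    family: str  # spherical | exponential | gaussian
    nugget: float
    sill: float
    range_: float

    def __post_init__(self) -> None:
        if self.family not in ("spherical", "exponential", "gaussian"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError("require 0 ≤ nugget ≤ sill and range > 0")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at lag(s) h; γ(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        if self.family == "spherical":
            r = np.clip(h / self.range_, 0.0, 1.0)
            struct = psill * (1.5 * r - 0.5 * r**3)
        elif self.family == "exponential":
            struct = psill * (1.0 - np.exp(-3.0 * h / self.range_))
        else:
            struct = psill * (1.0 - np.exp(-3.0 * h**2 / self.range_**2))
        return np.where(h > 0, self.nugget + struct, 0.0)


def empirical_variogram(
    xy: np.ndarray, values: np.ndarray, n_lags: int = 12, max_lag: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical semivariogram (lag centers, mean semivariance)."""
    xy = np.asarray(xy, float)
    values = np.asarray(values, float)
    d = pdist(xy)
    g = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = d.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    centers, gammas = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (d > lo) & (d <= hi)
        if mask.sum() >= 1:
            centers.append((lo + hi) / 2.0)
            gammas.append(g[mask].mean())
    return np.array(centers), np.array(gammas)


def fit_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    family: str = "spherical",
    n_lags: int = 12,
    max_lag: float | None = None,
) -> VariogramModel:
    """Least-squares fit of a variogram family to the empirical semivariogram."""
    xy = np.asarray(xy, float)
    values = np.asarray(values, float)
    if len(values) < 10:
        raise ValueError("variogram fitting needs at least 10 samples")
    if np.ptp(values) == 0.0:
        warnings.warn("all sample values identical; degenerate flat variogram",
                      stacklevel=2)
        span = float(pdist(xy).max()) or 1.0
        return VariogramModel(family, 0.0, 0.0, span)

    lags, gammas = empirical_variogram(xy, values, n_lags, max_lag)

    def model(h, nugget, psill, rng):
        return VariogramModel(family, nugget, nugget + psill, rng).gamma(h)

    var0 = float(values.var()) or 1.0
    r0 = float(lags.max()) / 2.0
    try:
        popt, _ = curve_fit(
            model,
            lags,
            gammas,
            p0=[0.0, var0, r0],
            bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        nugget, psill, rng = popt
    except RuntimeError:  # fall back to moment estimates
        nugget, psill, rng = 0.0, var0, r0
    return VariogramModel(family, float(nugget), float(nugget + psill), float(rng))


def ordinary_kriging(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    target_xy: np.ndarray,
    variogram: VariogramModel,
) -> np.ndarray:
    """Ordinary kriging predictions at *target_xy*.

    Duplicate sample locations are averaged (with a warning) to keep the
    kriging system non-singular.
    """
    xy = np.asarray(sample_xy, float)
    z = np.asarray(sample_values, float)
    targets = np.asarray(target_xy, float)

    # deduplicate coincident samples by averaging their values
    key = np.round(xy, 9)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        warnings.warn("duplicate sample locations averaged before kriging",
                      stacklevel=2)
        sums = np.zeros(counts.shape[0])
        np.add.at(sums, inv, z)
        z = sums / counts
        keep = np.full(counts.shape[0], -1, dtype=int)
        for i, j in enumerate(inv):
            if keep[j] < 0:
                keep[j] = i
        xy = xy[keep]
    n = len(xy)

    if variogram.sill == 0.0:  # flat field: constant surface
        return np.full(len(targets), z.mean())

    gamma_ss = variogram.gamma(squareform(pdist(xy)))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma_ss
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0

    b = np.empty((n + 1, len(targets)))
    b[:n] = variogram.gamma(cdist(xy, targets))
    b[n] = 1.0
    try:
        w = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        w = np.linalg.lstsq(a, b, rcond=None)[0]
    return w[:n].T @ z
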