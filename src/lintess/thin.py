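"""Plain grid thinning of point sets.

Reduces a dense point set to one representative per grid cell — the cell's
centroid of member points, carrying the mean of any attached values.  Used
to keep kriging systems and K-function point counts tractable (e.g. dense
tessellation-unit centers, or oversampled outlet sets) while preserving the
coarse spatial distribution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["grid_thin"]


def grid_thin(
    xy: np.ndarray, cell_size: float, values: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """One representative point (and mean value) per occupied grid cell."""
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy) == 0:
        return xy, (None if values is None else np.asarray(values, float))
    keys = np.floor(xy / cell_size).astype(int)
    _, inv = np.unique(keys, axis=0, return_inverse=True)
    n_cells = inv.max() + 1
    counts = np.bincount(inv, minlength=n_cells).astype(float)
    cx = np.bincount(inv, weights=xy[:, 0], minlength=n_cells) / counts
    cy = np.bincount(inv, weights=xy[:, 1], minlength=n_cells) / counts
    out_xy = np.column_stack([cx, cy])
    out_vals = None
    if values is not None:
        values = np.asarray(values, dtype=float)
        out_vals = np.bincount(inv, weights=values, minlength=n_cells) / counts
    return out_xy, out_vals
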