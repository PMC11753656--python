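"""Network and planar K-functions with Monte Carlo CSR envelopes.

For points constrained to a street network the K-function counts, for each
point, the other points within *network* (shortest-path) distance h, scaled
by the inverse intensity ρ = n / l_T:

    K_obs(h) = (1/ρ) · (1/n) Σ_i N(h, p_i)

Complete spatial randomness (CSR) on a network means points placed uniform
by length; its K is estimated by Monte Carlo — the pointwise mean of K over
random replicates, with 5th/95th percentile envelopes bounding the random
regime at significance 0.05.  Observed curves above the upper envelope are
significantly clustered, below the lower significantly dispersed; between
the envelopes they are classified relative to the mean.

The planar K-function (Euclidean distances, ρ = n / area, no edge
correction) is provided as the comparator; under planar CSR, K(h) ≈ πh².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network import RoadNetwork

__all__ = [
    "PointPattern",
    "KFunctionConfig",
    "KFunctionResult",
    "NetworkDistances",
    "network_distances",
    "k_observed",
    "random_pattern",
    "csr_envelope",
    "classify",
    "planar_k",
    "network_k_analysis",
    "default_h_grid",
]

LABELS = (
    "significantly dispersed",
    "dispersed",
    "random",
    "clustered",
    "significantly clustered",
)


@dataclass(frozen=True)
class PointPattern:
    """A point set on a road network (edge id + measure) or in the plane."""

    xy: np.ndarray
    edge_ids: np.ndarray | None = None
    measures: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.xy)

    @property
    def on_network(self) -> bool:
        return self.edge_ids is not None

    @classmethod
    def from_network(
        cls, network: RoadNetwork, edge_ids: np.ndarray, measures: np.ndarray
    ) -> "PointPattern":
        edge_ids = np.asarray(edge_ids, dtype=int)
        measures = np.asarray(measures, dtype=float)
        xy = np.empty((len(edge_ids), 2))
        for i, (eid, m) in enumerate(zip(edge_ids, measures)):
            edge = network.edges[int(eid)]
            if not 0.0 <= m <= edge.length:
                raise ValueError(f"measure {m} outside edge {eid}")
            p = edge.geometry.interpolate(m)
            xy[i] = (p.x, p.y)
        return cls(xy, edge_ids, measures)

    @classmethod
    def planar(cls, xy: np.ndarray) -> "PointPattern":
        return cls(np.asarray(xy, dtype=float).reshape(-1, 2))


@dataclass(frozen=True)
class KFunctionConfig:
    h_grid: np.ndarray
    n_sim: int = 99
    significance: float = 0.05
    seed: int | None = None
    random_tolerance: float = 0.05  # |K_obs − mean| ≤ tol·mean → "random"

    def __post_init__(self) -> None:
        h = np.asarray(self.h_grid, dtype=float)
        if len(h) == 0 or np.any(h <= 0) or np.any(np.diff(h) <= 0):
            raise ValueError("h_grid must be strictly increasing and positive")
        object.__setattr__(self, "h_grid", h)
        if self.n_sim < 1:
            raise ValueError("n_sim must be ≥ 1")


class NetworkDistances:
    """Shortest-path distances on a network, reusable across point patterns.

    The all-pairs node distance matrix is computed once; a point-to-point
    distance is then the minimum over the four endpoint routings (plus the
    direct along-edge distance for points on the same edge).
    """

    def __init__(self, network: RoadNetwork):
        self.network = network
        self._node_index = {n: i for i, n in enumerate(sorted(network.nodes))}
        n = len(self._node_index)
        rows, cols, data = [], [], []
        g = network.graph()
        for u, v, w in g.edges(data="weight"):
            iu, iv = self._node_index[u], self._node_index[v]
            rows += [iu, iv]
            cols += [iv, iu]
            data += [w, w]
        mat = csr_matrix((data, (rows, cols)), shape=(n, n))
        self.node_dist = dijkstra(mat, directed=False)

    def pairwise(self, pattern: PointPattern) -> np.ndarray:
        """Symmetric matrix of shortest-path distances between the points."""
        if not pattern.on_network:
            raise ValueError("pattern points must lie on network edges")
        edges = self.network.edges
        eid = pattern.edge_ids
        for e in eid:
            if int(e) not in edges:
                raise ValueError(f"point references unknown edge {e}")
        u = np.array([self._node_index[edges[int(e)].u] for e in eid])
        v = np.array([self._node_index[edges[int(e)].v] for e in eid])
        a = pattern.measures.astype(float)  # distance to node u along edge
        b = np.array([edges[int(e)].length for e in eid]) - a  # to node v
        D = self.node_dist
        d = np.minimum.reduce(
            [
                a[:, None] + D[np.ix_(u, u)] + a[None, :],
                a[:, None] + D[np.ix_(u, v)] + b[None, :],
                b[:, None] + D[np.ix_(v, u)] + a[None, :],
                b[:, None] + D[np.ix_(v, v)] + b[None, :],
            ]
        )
        same = eid[:, None] == eid[None, :]
        along = np.abs(a[:, None] - a[None, :])
        d = np.where(same, np.minimum(d, along), d)
        np.fill_diagonal(d, 0.0)
        return d

    def diameter(self) -> float:
        finite = self.node_dist[np.isfinite(self.node_dist)]
        return float(finite.max()) if len(finite) else 0.0


def network_distances(network: RoadNetwork, pattern: PointPattern) -> np.ndarray:
    """One-shot pairwise network distance matrix (see :class:`NetworkDistances`)."""
    return NetworkDistances(network).pairwise(pattern)


def _k_from_distances(dists: np.ndarray, h_grid: np.ndarray, scale: float) -> np.ndarray:
    """K(h) = scale · Σ_{i≠j} 1[d_ij ≤ h], vectorised over the h grid."""
    iu = np.triu_indices(dists.shape[0], k=1)
    pair = np.sort(dists[iu])
    counts = 2.0 * np.searchsorted(pair, h_grid, side="right")
    return scale * counts


def k_observed(
    network: RoadNetwork,
    pattern: PointPattern,
    h_grid: np.ndarray,
    dist_calc: NetworkDistances | None = None,
) -> np.ndarray:
    """Observed network K-function over *h_grid* (intensity ρ = n/l_T)."""
    if pattern.n < 2:
        raise ValueError("K-function needs at least 2 points")
    calc = dist_calc or NetworkDistances(network)
    dists = calc.pairwise(pattern)
    l_t = network.total_length
    return _k_from_distances(dists, np.asarray(h_grid, float), l_t / pattern.n**2)


def random_pattern(
    network: RoadNetwork, n: int, seed: int | np.random.Generator | None = None
) -> PointPattern:
    """CSR on the network: n points i.i.d. uniform by length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eids = sorted(network.edges)
    lengths = np.array([network.edges[e].length for e in eids])
    if n == 0:
        return PointPattern(np.empty((0, 2)), np.empty(0, int), np.empty(0))
    cum = np.cumsum(lengths)
    pos = rng.uniform(0.0, cum[-1], size=n)
    idx = np.searchsorted(cum, pos, side="right")
    measures = pos - np.concatenate([[0.0], cum[:-1]])[idx]
    edge_ids = np.array([eids[i] for i in idx])
    return PointPattern.from_network(network, edge_ids, measures)


def csr_envelope(
    network: RoadNetwork,
    n: int,
    config: KFunctionConfig,
    dist_calc: NetworkDistances | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise Monte Carlo mean and 5%/95% envelopes of K under CSR."""
    calc = dist_calc or NetworkDistances(network)
    rng = np.random.default_rng(config.seed)
    sims = np.empty((config.n_sim, len(config.h_grid)))
    for s in range(config.n_sim):
        pat = random_pattern(network, n, rng)
        sims[s] = k_observed(network, pat, config.h_grid, calc)
    lo = 100.0 * config.significance
    return (
        sims.mean(axis=0),
        np.percentile(sims, lo, axis=0),
        np.percentile(sims, 100.0 - lo, axis=0),
    )


def classify(
    k_obs: np.ndarray,
    k_mean: np.ndarray,
    k_lower: np.ndarray,
    k_upper: np.ndarray,
    random_tolerance: float = 0.05,
) -> list[str]:
    """Per-h pattern labels relative to the CSR mean and envelopes."""
    labels = []
    for k, m, lo, up in zip(k_obs, k_mean, k_lower, k_upper):
        if k > up:
            labels.append("significantly clustered")
        elif k < lo:
            labels.append("significantly dispersed")
        elif abs(k - m) <= random_tolerance * m:
            labels.append("random")
        elif k > m:
            labels.append("clustered")
        else:
            labels.append("dispersed")
    return labels


@dataclass
class KFunctionResult:
    """Observed K, CSR mean and envelopes, and per-h pattern labels."""

    h: np.ndarray
    k_obs: np.ndarray
    k_mean: np.ndarray
    k_lower: np.ndarray
    k_upper: np.ndarray
    labels: list[str] = field(default_factory=list)
    l_t: float = 0.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.k_lower > self.k_mean + 1e-12) or np.any(
            self.k_mean > self.k_upper + 1e-12
        ):
            raise ValueError("envelopes must bracket the Monte Carlo mean")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.h,
                "k_obs": self.k_obs,
                "k_mean": self.k_mean,
                "k_lower": self.k_lower,
                "k_upper": self.k_upper,
                "label": self.labels,
            }
        )

    def plot(self, ax=None, title: str | None = None):
        """Observed vs expected K with the CSR envelope band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(
            self.h, self.k_lower, self.k_upper, alpha=0.25, color="grey",
            label="Exp (5.0% envelopes)",
        )
        ax.plot(self.h, self.k_mean, "r--", label="Exp (mean)")
        ax.plot(self.h, self.k_obs, "b-", label="Obs")
        ax.set_xlabel("distance h (m)")
        ax.set_ylabel("K(h)")
        if title:
            ax.set_title(title)
        ax.legend()
        return ax


def network_k_analysis(
    network: RoadNetwork, pattern: PointPattern, config: KFunctionConfig
) -> KFunctionResult:
    """Observed network K with Monte Carlo CSR envelopes and labels."""
    calc = NetworkDistances(network)
    k_obs = k_observed(network, pattern, config.h_grid, calc)
    k_mean, k_lower, k_upper = csr_envelope(network, pattern.n, config, calc)
    labels = classify(k_obs, k_mean, k_lower, k_upper, config.random_tolerance)
    return KFunctionResult(
        h=np.asarray(config.h_grid, float),
        k_obs=k_obs,
        k_mean=k_mean,
        k_lower=k_lower,
        k_upper=k_upper,
        labels=labels,
        l_t=network.total_length,
        rho=pattern.n / network.total_length,
    )


def planar_k(
    pattern: PointPattern,
    region: tuple[float, float, float, float],
    h_grid: np.ndarray,
) -> np.ndarray:
    """Planar K-function (Euclidean, no edge correction; ρ = n/area)."""
    if pattern.n < 2:
        raise ValueError("K-function needs at least 2 points")
    x0, y0, x1, y1 = region
    xy = pattern.xy
    if np.any(xy[:, 0] < x0) or np.any(xy[:, 0] > x1) or np.any(
        xy[:, 1] < y0
    ) or np.any(xy[:, 1] > y1):
        raise ValueError("points must lie inside the region")
    area = (x1 - x0) * (y1 - y0)
    diff = xy[:, None, :] - xy[None, :, :]
    dists = np.hypot(diff[..., 0], diff[..., 1])
    return _k_from_distances(dists, np.asarray(h_grid, float), area / pattern.n**2)


def default_h_grid(network: RoadNetwork, n_steps: int = 50) -> np.ndarray:
    """n_steps equal distance steps up to half the network diameter."""
    diam = NetworkDistances(network).diameter()
    return np.linspace(diam / 2.0 / n_steps, diam / 2.0, n_steps)
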