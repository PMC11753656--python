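import numpy as np
import pytest
from shapely.geometry import LineString

from lintess.network import TessellationConfig, build_network, tessellate
from lintess.synth import gen_grid_network


@pytest.fixture
def single_edge_network():
    """One straight 100 m edge."""
    return build_network([(LineString([(0.0, 0.0), (100.0, 0.0)]), {})])


@pytest.fixture
def grid_network():
    """3x3 lattice, 100 m spacing: 9 nodes, 12 edges."""
    return gen_grid_network(3, 3, 100.0)


@pytest.fixture
def junction_network():
    """A 50 m central edge with two 30 m branches at each end.

    With 10 m equal-length units, an event at the center of the middle
    unit expands to rings of 2, 2 and 4 units at steps 1, 2 and 3 —
    the canonical worked example of the step-limited expansion.
    """
    segs = [
        (LineString([(0.0, 0.0), (50.0, 0.0)]), {}),  # central, 5 units
        (LineString([(0.0, 0.0), (-30.0, 0.0)]), {}),
        (LineString([(0.0, 0.0), (0.0, 30.0)]), {}),
        (LineString([(50.0, 0.0), (80.0, 0.0)]), {}),
        (LineString([(50.0, 0.0), (50.0, 30.0)]), {}),
    ]
    return build_network(segs)


@pytest.fixture
def junction_tess(junction_network):
    cfg = TessellationConfig(defined_length=10.0, mode="equal_length")
    return tessellate(junction_network, cfg)


def random_network(rng, n_nodes=8, extra_edges=3, scale=1000.0):
    """A random connected planar-coordinate network (tree + chords)."""
    pts = rng.uniform(0.0, scale, size=(n_nodes, 2))
    feats = []
    for i in range(1, n_nodes):
        j = int(rng.integers(i))
        feats.append((LineString([tuple(pts[j]), tuple(pts[i])]), {}))
    for _ in range(extra_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        if np.hypot(*(pts[i] - pts[j])) > 1e-6:
            feats.append((LineString([tuple(pts[i]), tuple(pts[j])]), {}))
    return build_network(feats)
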