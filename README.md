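# lintess

Linear-tessellation analysis of street networks: network kernel density
estimation, the network K-function, and an accessibility/income overlay that
maps "food desert" risk.

## The problem

Access to everyday amenities — healthy food outlets in the motivating use
case — happens *along streets*, not across free Euclidean space. Planar
density estimates and planar point-pattern statistics therefore tend to
overstate how well-served a neighbourhood is and to over-detect clustering.
`lintess` carries the raster idea into network space: every road edge is
split into short **basic linear units** with explicit topology, and all
statistics are computed on that unit graph.

Two tessellation modes exist. In *equal-length* mode each edge is cut into
units of at most a defined length `l_e` (default 100 m). In *isochronous*
mode the target unit length on edge *i* is

```
L_i = l_e · f_i ,   f_i = v_i / l_e  (v_i > 0)   or   v_min / l_e  (v_i = 0)
```

i.e. `L_i = v_i` metres, so traversing one unit takes one second at the
edge's mode speed `v_i` (m/s), with a fallback minimum speed `v_min`
(default 0.8 m/s, a walking pace) on unobserved edges. Per-edge speeds come
from GPS trajectories (interval speeds smoothed with a random-walk Kalman
filter, averaged per edge) or from a constant per mode (e.g. metro).

On the tessellation:

- **Network KDE** — each event point is snapped to its nearest unit and
  expanded breadth-first over the unit adjacency up to a step threshold τ;
  a unit at step *d* receives `(1/τ²)·k(d/τ)` with the quartic kernel
  `k(x) = (3/4)(1 − x²)`. On isochronous units a step is one second, so τ
  is a travel-time standard (walk 1800 s, bicycle 900 s, taxi 600 s,
  metro 1200 s by default). The *scope of accessibility* is the
  length-weighted share of units with non-zero density.
- **Network K-function** — `K_obs(h) = (1/ρ)·(1/n)·Σᵢ N(h, pᵢ)` with
  shortest-path distances and intensity `ρ = n/l_T`; complete spatial
  randomness (uniform-by-length points) is simulated to get pointwise Monte
  Carlo mean and 5%/95% envelopes, and each distance is labelled random /
  (significantly) clustered / (significantly) dispersed.
- **Income overlay** — per-capita income is derived from house prices via
  the price-to-income ratio `I = P_h·A_h / R` (defaults `A_h = 36.7` m²,
  `R = 17.1`, low-income threshold 27,600/year); income and network-KDE
  surfaces are kriged to a common grid, binarised (KDE > 0; income strictly
  above threshold), and cross-combined into patterns HH/HL/LH/LL with risk
  levels 0–3 — LL (no access, low income) is the food-desert class.

Planar comparators (grid KDE, planar K) and a fully seeded synthetic-city
generator (lattice streets, per-mode speeds, Thomas-clustered amenities,
noisy GPS traces, a center-decaying price field) are included, so the whole
pipeline runs without any external data.

## Worked example

```python
import numpy as np
from lintess import *
from lintess.synth import gen_city, SyntheticCityConfig
from lintess.thin import grid_thin

city = gen_city(SyntheticCityConfig(seed=1))        # ~1 km synthetic city
net = city.network

tess = tessellate(net, TessellationConfig(mode="isochronous",
                                          transport_mode="walk"))
print(f"tessellation: {len(tess)} isochronous units over "
      f"{net.total_length/1000:.1f} km of streets")

field = network_kde(tess, [tuple(p) for p in city.amenities.xy],
                    KDEConfig(180, transport_mode="walk"))
print(f"walk-mode network KDE (tau = 180 s): "
      f"scope = {accessibility_scope(field):.1f}%")

res = network_k_analysis(net, city.amenities,
                         KFunctionConfig(np.linspace(60, 900, 15),
                                         n_sim=99, seed=2))
print("label at smallest h:", res.labels[0],
      "| K_obs:", round(res.k_obs[0], 1),
      "upper env:", round(res.k_upper[0], 1))

incomes = income_from_price(city.price_values)
grid = PlanarGrid.from_bounds(net.bounds, 100.0)
inc_grid = interpolate_to_grid(city.price_xy, incomes, grid)
centers = np.array([tess.units[int(i)].center for i in field.ids])
kde_grid = interpolate_to_grid(*grid_thin(centers, 100.0, field.values), grid)
pm = overlay_patterns(reclassify(kde_grid, "kde"),
                      reclassify(inc_grid, "income"), grid)
props = pattern_proportions(pm)
print("pattern proportions (%):", {k: round(v, 1) for k, v in props.items()})
```

prints (seed 1):

```
tessellation: 22942 isochronous units over 18.0 km of streets
walk-mode network KDE (tau = 180 s): scope = 24.6%
label at smallest h: significantly clustered | K_obs: 2160.0 upper env: 241.0
pattern proportions (%): {'HH': 46.9, 'HL': 2.5, 'LH': 12.3, 'LL': 38.3}
```

Read: a 3-minute walking standard reaches 24.6% of the street length from
the (deliberately center-clustered) amenities; the K-function flags that
clustering as significant (K_obs far above the CSR envelope); and 38% of
grid cells end up in the LL food-desert class — all of them in the
amenity-poor, low-price periphery the generator built.

The same stages are available from the shell:

```sh
lintess simulate --seed 1 --out-dir city
lintess kde city/network.geojson city/amenities.geojson --tau 180
lintess kfunction city/network.geojson city/amenities.geojson
lintess run config.json          # full five-stage pipeline from JSON config
```

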