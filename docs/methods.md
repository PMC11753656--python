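# Methods

This note documents the models implemented in `lintess`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## The linear tessellation

A road network is an undirected graph of nodes (merged polyline endpoints,
snap tolerance 0.01 m) and edges carrying planar metric geometry, length,
and a per-mode speed table. Inputs must be in a projected metric CRS; the
package does not reproject, it only warns when a bounding box looks like
lon/lat degrees.

Each edge is split into basic linear units. The target unit length is the
defined length `l_e` (equal-length mode, default 100 m) or the edge's mode
speed `v_i` (isochronous mode: one second of travel per unit), with
`v_min = 0.8` m/s substituted where the speed is missing or zero. Because
an edge length is rarely an exact multiple of the target, each edge is
divided into `ceil(length/target)` units of equal length — units stay
homogeneous *within* an edge, lengths never exceed the target, and
isochronous traversal times are ≤ 1 s rather than exactly 1 s on such
edges. Exact one-second units occur only when the edge length is a
multiple of `v_i`.

Topology: consecutive units on an edge are adjacent, and all units
incident to a shared network node are pairwise adjacent. The second rule
is a deliberate choice — it makes breadth-first step counts well defined
through junctions of any degree, at the cost of letting one step cross a
junction "diagonally" between two units that only meet at the node.
Networks are treated as undirected; one-way restrictions, turn penalties
and multi-modal transfers are out of scope.

Point snapping is nearest-unit in Euclidean distance with ties broken by
smallest unit id, which makes every downstream result deterministic.

## Speed estimation

Raw interval speeds (consecutive-fix distance over elapsed time) are
filtered by a one-dimensional Kalman filter whose state is the true speed
under a random-walk transition (defaults: process variance 0.1, measurement
variance 1.0; with measurement variance → 0 the filter returns its input).
The filter acts on speeds, not positions — the simplest defensible state
model when nothing more is specified; both variances are exposed.
Map-matching is nearest-edge assignment of interval midpoints within a
configurable snap distance (default 50 m); there is no HMM matching, which
is adequate at the scale of the bundled generators but would mis-assign
intervals in dense parallel-street networks. Edge speed is the mean of
assigned smoothed intervals; uncovered edges stay out of the table and
fall back to `v_min` downstream. Intervals that span a junction measure
the chord rather than the path and bias speeds low; with block lengths
well above the per-interval displacement this bias is below the 2%
recovery tolerance used in the tests (1 km blocks, 36 m intervals: ~4% of
intervals affected).

## Network KDE

Events are snapped to source units and expanded breadth-first up to a step
threshold τ. A unit first reached at step `d ≤ τ` contributes
`(1/τ²)·k(d/τ)` per source, `k(x) = (3/4)(1 − x²)`, summed over sources
(the field is exactly linear in the events). Choices worth stating:

- The kernel argument is the **step ratio** `d/τ`, not a metric ratio.
  On an isochronous tessellation steps are seconds, so τ is a travel-time
  standard. Metric shortest-path distances (center-to-center half-length
  sums along the expansion) are computed and reported but do not enter the
  kernel.
- The source unit itself receives weight at `d = 0` by default
  (`include_source=False` gives the alternative).
- The `1/τ²` normalisation is kept as written even though the network
  domain is one-dimensional; all comparisons here are within one τ, where
  it is a constant factor.
- Units at exactly step τ are reached but receive weight `k(1) = 0`.
  Consequently the *scope of accessibility* — the length-weighted share of
  units with **non-zero** value — counts steps ≤ τ−1, not the full reach.
- No equal-split correction at junctions: the expansion radiates into all
  branches at full weight. This over-weights dense junction neighbourhoods
  relative to an Okabe-style equal-split kernel and is a fidelity choice,
  not an oversight.

Default step thresholds are the mode time standards in seconds — walk
1800 (30 min), bicycle 900 (15 min), taxi 600 (10 min), metro 1200
(20 min). The planar comparator evaluates the same kernel with Euclidean
distance on a grid (default cell 100 m, matching `l_e`); its default
bandwidths are speed × standard: 1440, 3240, 2580 and 1320 m.

## Network K-function

For n points on a network of total length `l_T`,
`K_obs(h) = (1/ρ)·(1/n)·Σᵢ N(h, pᵢ)` with `ρ = n/l_T` and shortest-path
distances; `K_obs` saturates at `l_T(n−1)/n`. Point-to-point distances are
the minimum over the four endpoint routings of each point's edge plus the
direct along-edge distance for same-edge pairs; the all-pairs node matrix
is computed once (scipy Dijkstra) and reused across Monte Carlo
replicates.

The CSR reference is simulated, not analytic: `n_sim` (default 99)
uniform-by-length patterns give the pointwise mean and 5th/95th percentile
envelopes (significance 0.05). Labels per h: above the upper envelope →
significantly clustered; below the lower → significantly dispersed;
within a relative tolerance of the mean (default `|K−mean| ≤ 0.05·mean`,
configurable — "nearly coincides" has no canonical numeric rule) → random;
otherwise clustered/dispersed by the side of the mean. The planar
K-function uses `ρ = n/area` and no edge correction, which inflates
apparent clustering near region borders; it is a comparator, not a
corrected estimator. The default h grid is 50 equal steps to half the
network diameter.

## Income, kriging, overlay

Income is `I = P_h·A_h/R` with housing-per-capita `A_h = 36.7` m² and
price-to-income ratio `R = 17.1`; the low-income threshold is 27,600 per
year and the income binarisation is **inclusive** at the bound (exactly
27,600 classifies as low). Accessibility binarises as KDE > 0.

Surfaces are produced by ordinary kriging: empirical semivariogram in 12
lag bins to half the maximum pairwise distance, least-squares fit of a
spherical (default), exponential or gaussian model under the
practical-range convention, then the standard OK system with a Lagrange
multiplier (weights sum to one; exact interpolation at samples when the
nugget is zero). Duplicate sample locations are averaged with a warning; a
zero-variance sample set yields a flat surface. Network-KDE values are
supported on unit centers; before kriging they are grid-thinned (one
cell-mean representative per 100 m cell) to keep the kriging system small
— kriging cost is cubic in the sample count. Kriged densities can
undershoot zero and are clamped to 0 before binarisation, since both
densities and incomes live on [0, ∞).

The overlay maps (access, income) bits to patterns HH (1,1), HL (1,0),
LH (0,1), LL (0,0) with risk levels 0/1/2/3; LL — no amenity access and
low income — is the food-desert class. Proportions are cell-count shares
and always partition to 100%.

## Synthetic city

The generator produces, from one seed: a rows×cols lattice network
(default 10×10, 100 m spacing, ≈1 km across, 18 km of streets); per-edge
mode speeds drawn around the mode averages (walk 0.8, bicycle 3.6, taxi
4.3, metro 1.1 m/s; sd = 10% of the mean); amenities from a uniform or
Thomas process whose offspring are displaced *along network paths* within
the cluster radius (default 8 parents, radius 150 m, 60 points), with
parents optionally confined to the central third to build a center-rich
city; GPS traces as constant-speed random walks with isotropic Gaussian
fix noise (default 2 m, 10 s fixes); and house prices
`P(d) = P₀·exp(−d/decay)` plus noise, floored at zero (P₀ = 50,000 per
m², decay 300 m, 500 points — at these values income crosses the
low-income threshold ≈ 400 m from the center, inside the ~640 m corner
radius, so the city genuinely contains both classes).

Because the city is ~1 km across, the full 30-minute walking standard
would cover it entirely; the end-to-end demonstrations therefore use a
3-minute standard (τ = 180 one-second steps, ≈ 145 m of network reach)
chosen from the city geometry so the amenity-rich core is served and the
periphery is not. What the passing end-to-end test shows is that the
pipeline recovers the *planted* structure — LL cells appear and lie in the
generated amenity-poor, low-price periphery; it does not validate speed
heterogeneity from real congestion, irregular street topology, or
non-monotone income fields, none of which the generator produces.

## Numerical conventions and degenerate inputs

Edge lengths must be positive; length bookkeeping uses 1e-6 relative
tolerance. Snap ties (units and edges) resolve to the smallest id. BFS
levels are first-visit levels, which equal unweighted shortest-path
distances (tested exactly against an independent all-pairs computation).
Network-space τ must be an integer step count. Envelope percentiles are
pointwise; with `n_sim = 1` the envelopes collapse onto the single
replicate. An empty speed table, an empty feature collection, or a trace
matching no edge warn rather than fail; zero-length edges, non-increasing
timestamps, points outside the planar-K region, and mismatched overlay
grids fail loudly.

## Known limitations

No one-way streets, turn restrictions or transfers; no HMM map-matching;
no junction equal-split kernel; planar K without edge correction; kriging
assumes second-order stationarity that a sharp urban gradient only
approximates; the acceptance-scale experiments run on lattice networks,
which have none of the degree heterogeneity of real street graphs.
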