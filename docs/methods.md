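# Methods

This note documents the models, numerical choices and limitations of
`dynaccess`: a pipeline measuring population accessibility to emergency
departments (EDs) and quantifying when and where residential ("static")
population data over- or underestimate population shares relative to
hourly mobile-network-derived ("dynamic") population data.

## Units and geometry

All coordinates are planar projected metres; travel times are minutes;
populations are persons (fractional after grid splitting). Geometry is
exchanged as GeoJSON but never reprojected: a projected CRS is assumed
throughout, as is standard for national grids.

## Road network and routing

Road segments carry a polyline and a speed limit (km/h). Connectivity
follows national road-database conventions: two segments are connected
where they share an exact vertex coordinate, so segments are split
wherever an interior vertex coincides with a vertex of another segment.
Geometric crossing detection is deliberately not used — it would falsely
connect grade-separated crossings (bridges, overpasses). Walking roads
are removed with a strict reading of the 10 km/h limit (< 10 removed,
= 10 kept). Each remaining segment becomes one undirected edge with
weight `length_m / (speed_kmh·1000/60)` minutes; parallel edges collapse
to the fastest. One-way restrictions, traffic, and weather are out of
scope.

Cell centroids are snapped to the Euclidean-nearest junction node, with
a 5 000 m eligibility cut-off; the cut-off is measured to the nearest
*node* (one consistent metric), not the nearest edge. Cells beyond it,
or in components containing no ED, are flagged unreachable and excluded
from every later total — exclusion on both sides is required for the
ratio identities below to hold. Closest-facility times come from one
Dijkstra per ED; exact shortest paths, no hierarchical approximation.
All ties (equidistant snap nodes, equal travel times) break toward the
lowest identifier so runs are reproducible.

## Grid fusion

The static grid is homogeneous; the dynamic grid is nested with side
ratios that are powers of 2 and borders aligned to the static grid —
fusion validates this and raises on any partially overlapping pair.
Where a dynamic cell is larger, covered static populations are summed.
Where it is smaller, the static cell's population is divided equally
among the covering quarters, recursively for 4^k subdivision — a
uniform within-cell density assumption; no dasymetric refinement.
Populations are kept as reals so total static population is conserved
exactly (asserted to 1e-9 in tests). An aggregated cell takes the urban
class holding the majority of its static population (ties broken
urban > densely populated > rural); a split quarter inherits its
parent's class.

## Temporal ratios

Dynamic population at a stratum is the arithmetic mean of all matching
hourly counts per cell (robust to unequal numbers of pooled timestamps;
identical to pooling when panels are balanced). Strata are hour ×
weekday/weekend, month (pooling hours), and month × hour — the last is
used for the catchment comparison at 13:00 in January and July.

Because static and dynamic totals differ (operator extrapolation), the
comparison uses shares: each dataset normalized by its own total over
reachable cells. Per band and stratum, `ratio = static_share /
dynamic_share`; per catchment, `diff_pct = (ratio − 1)·100`. Ratios with
zero dynamic share are reported as missing, never as infinities. Exact
identities verified by test: multiplying all dynamic counts by any c > 0
leaves every ratio unchanged; when dynamic ≡ c × static every ratio is
1 and every diff_pct is 0; the dynamic-share-weighted mean of band
ratios is 1 in every stratum.

Accessibility bands are half-open, [0,10), [10,20), [20,30), [30,60),
[60,∞) minutes — the conventional exhaustive choice; boundary handling
is otherwise arbitrary.

## Spatial statistics

Catchments are represented by static-population-weighted centroids of
their member cells (reflecting where the served population sits, which
is what the distance conceptualization should weight). Weights are raw
inverse distance, `w_ij = 1/d_ij` for `0 < d_ij ≤ threshold`, with the
threshold chosen automatically as the largest nearest-neighbour distance
— the minimal cut-off leaving no catchment neighbourless. Rows are not
standardized (a config switch enables it); because Moran's I normalizes
by S0, the distance unit cancels, which a test asserts.

Moran's I reports two p-values: a two-sided permutation pseudo p
(999 permutations by default, seeded, extremeness measured as distance
from the null expectation −1/(n−1)) and the analytic z-test under the
randomization assumption; the permutation p is primary. The analytic
variance needs n ≥ 4 and is reported as NaN below that. A constant
surface is an error ("I undefined"), which the pipeline records as a
missing result — the identity scenario exercises this path.

One-way ANOVA is computed from the explicit between/within
sum-of-squares decomposition (cross-checked against
`scipy.stats.f_oneway`), with the degenerate zero-within-variance case
reported as F = ∞, p = 0 (or F = 0, p = 1 when the data are entirely
constant). Tukey HSD uses `scipy.stats.tukey_hsd` (Tukey–Kramer for
unequal n); each pair is reported as "difference ± half-width, p", the
± term being the 95 % family-wise half-width, so the interval excludes
zero exactly when the adjusted p < 0.05.

## Synthetic study regions

The generator emulates the *structure* of the real input stack, not its
geography:

- **Static grid** — `grid_extent²` cells of 1 km² with density
  `base + peak·exp(−d²/2σ²)` around the centre (defaults 3 + 600,
  σ = 2.5 cells): a dense urban core, sparse periphery.
- **Dynamic grid** — quadtree refinement: a cell splits into 4 while
  every child would hold at least `privacy_floor` (default 5) persons at
  every stratum, down to quarter-cells (0.25 km²). This reproduces the
  observed privacy mechanism — small cells in dense areas, large in
  sparse ones, areas differing by powers of 4, borders aligned — without
  device-level simulation. `grid_extent` must be a power of two so the
  quadtree stays border-aligned. If even the root fails the floor, the
  single root cell is emitted rather than an error.
- **Movement** — July first relocates `vacation_fraction` of core
  residents equally to the coastal boundary-ring cells (all hours;
  vacation stays are day-long); then weekday hours 08–17 move
  `commuting_fraction` of each non-core cell's current residents into
  core cells, allocated proportionally to core resident counts. Totals
  are conserved at every stratum; counts are scaled by `operator_scale`
  and optionally Poisson-perturbed (off by default so closed-form checks
  are exact).
- **EDs** — placed at cell centres by farthest-point sampling (a
  dispersed national network) or clustered at the core; levels 1–3
  assigned by centrality with proportions 0.25/0.35/0.40.
- **Classes** — urban / densely populated / rural by distance band from
  the centre (the urban band always contains the commuting core);
  deriving classes from commuting statistics is out of scope — labels
  are input data.

Two preset scenarios define the study conditions. The *commuting*
scenario (16×16 km, commuting_fraction 0.3, 3 core EDs, slower speed
set, no noise) isolates the office-hour signature: the 0–10 min band's
ratio drops below 1 while middle bands rise above it. The *vacation*
scenario (vacation_fraction 0.35, commuting off, operator_scale 1.4,
Poisson noise, 16 dispersed EDs) isolates the seasonal signature: July
catchment differences are strongly clustered (core positive, coast
negative) while January carries only unstructured Poisson noise. The
16×16 extent keeps the full pipeline and permutation tests in seconds
while leaving every spatial scale (quarter-cells to 2 km aggregates)
populated.

What the generator does *not* emulate: realistic geography or road
topology (a lattice, not a network with bridges and ferries), hourly
commuting ramps (the office-hour window is a step function),
device-ownership bias, or the operator's actual extrapolation model —
`operator_scale` is a configurable stand-in, and scale invariance of the
ratios makes its exact value immaterial. Passing tests therefore
demonstrate correctness of the arithmetic and the qualitative
recoverability of implanted movement patterns, not calibration to any
real population.

## Known limitations

- With 16 catchments the Moran permutation test has modest power: the
  July clustering is detected at the preset seed, but detection varies
  across seeds at this problem size (the January noise-only p-value is,
  by construction, uniform across seeds).
- Quadtree refinement stops one level below the static resolution;
  deeper refinement would require an explicit sub-cell density model.
- The 5 000 m snap eligibility uses node distance; edge distance is a
  defensible alternative and would admit slightly more cells.
- Catchment representative points are population-weighted centroids;
  geometric centroids would shift inverse-distance weights somewhat for
  elongated catchments.
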