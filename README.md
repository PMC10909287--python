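# dynaccess

Spatial accessibility to emergency departments (EDs), measured with both
**static** (residential/census) and **dynamic** (hourly
mobile-network-derived) population data.

Health-care planners usually estimate how many people can reach an ED
within a travel-time threshold from residential registers. But people
move: they commute toward city centres on weekday office hours and leave
the cities for coastal and rural areas in the vacation season. `dynaccess`
implements the full analysis chain needed to quantify where and when the
stationary-population assumption over- or underestimates population
shares — and a synthetic-data generator that reproduces the statistical
structure of the proprietary inputs such studies rely on (a homogeneous
1 km² census grid, a privacy-floored multi-resolution mobile-phone grid,
a national road database with speed limits).

## Method

1. **Road network** — polyline segments are split at shared vertices,
   walking roads (< 10 km/h) removed, and each segment becomes an
   undirected edge weighted by travel time
   `t = length / speed`. Cell centroids within 5 000 m of a junction are
   snapped to it; the rest are omitted, as in national practice.
2. **Closest facility** — per cell, `t_i = min_e d(cell_i, ED_e)` by
   Dijkstra shortest paths; the argmin defines the ED **catchment
   areas**, which partition the reachable cells.
3. **Grid fusion** — the homogeneous static grid and the nested
   variable-resolution dynamic grid are merged on the dynamic geometry:
   static cells covered by a larger dynamic cell are summed; static
   cells split by smaller dynamic cells are divided equally among the
   4ᵏ quarters. Total static population is conserved exactly.
4. **Temporal ratios** — for accessibility band *b* (0–10, 10–20, 20–30,
   30–60, > 60 min) and temporal stratum *s* (hour × weekday/weekend,
   month), the statistic is

   `ratio(b, s) = static_share(b) / dynamic_share(b, s)`

   with each dataset normalized by its own total over reachable cells,
   so the ratio is invariant to the operator-extrapolation scale of the
   dynamic counts. Ratio > 1: residential data overestimate the share of
   people present; < 1: underestimate. The same arithmetic per catchment
   gives `diff_pct = (ratio − 1)·100` per ED.
5. **Spatial statistics** — global Moran's I with inverse-distance
   weights (`w_ij = 1/d_ij` within the smallest cut-off giving every
   catchment a neighbour) tests whether catchment differences cluster in
   space, with a permutation p-value and the analytic randomization
   z-test; one-way ANOVA and Tukey HSD compare hospital levels 1–3.

## Worked example

`python examples/04_catchment_statistics.py` runs the vacation scenario
(July outflow of 35 % of urban-core residents to the coastal ring,
Poisson observation noise, dynamic totals 1.4× static) and prints:

```
January 13:00  mean catchment diff_pct by ED level: {1: -0.1, 2: 0.4, 3: 6.4}
July 13:00  mean catchment diff_pct by ED level: {1: 8.5, 2: -25.2, 3: -82.4}
January: Moran's I = 0.20 (expected -0.067), permutation p = 0.126
July: Moran's I = 0.36 (expected -0.067), permutation p = 0.035
July ANOVA across ED levels: F(2,13) = 56.47, p = 3.9e-07
  Tukey level 1 vs 2: +33.7 ± 23.5 pct points, p = 0.006
```

In January the catchment differences are small and not significantly
clustered; in July residential data overestimate the population present
in the large urban (level 1) catchments by ~9 % and underestimate the
small coastal (level 3) catchments by ~82 %, the clustering is
significant, and the between-level differences survive the family-wise
Tukey correction — the equity pattern the method is designed to expose.
The other examples show the generator's grid structure, the
population-by-band accessibility table, and the weekday commuting
signature in the hourly ratio curves.

A thin CLI wraps the same library:

```
dynaccess simulate --out sim/ --seed 1
dynaccess run --config cfg.yaml --seed 1 --out out/
```

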