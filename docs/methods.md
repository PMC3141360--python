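# Methods

## Risk model

The pipeline operationalises Crichton's risk triangle — risk requires a
hazard, something exposed to it, and vulnerability of the exposed — as
a per-zone weighted overlay:

```
h_i   = zonal mean of the UHI raster over zone i          (°C, raw)
v_i   = w_old·old_i* + w_ill·ill_i* + w_flats·flats_i* + w_dens·dens_i*
r_i   = w_haz·h_i* + w_vuln·v_i
```

where `x*` denotes the standardized layer `max(x, 0) / max_j max(x_j, 0)`
and the default weights are 0.25 each within the vulnerability group and
0.5/0.5 at the top level. All layers therefore live on [0, 1] with
maximum exactly 1, and `r_i ∈ [0, 1]` by convexity.

Assumptions worth stating explicitly:

* **Single-scene hazard.** The hazard is one raster snapshot of surface
  UHI magnitude; the spatial pattern of an urban heat island is broadly
  stable across meteorological conditions, so a single heatwave-day
  scene is used as the spatial template. No multi-scene averaging, no
  surface-to-air temperature conversion: only the *relative* spatial
  pattern matters, since standardization removes the absolute scale.
* **Households as the exposure unit.** All vulnerability layers count
  households, not persons; persons enter only through the generator's
  population targets (2.4 persons per household).
* **Equal weights by default.** Weighting is configurable but the
  defaults are deliberately uniform: any non-uniform choice injects
  judgement the method itself cannot justify.

## Geometry and zonal statistics

Coordinates are planar metres (a projected national-grid-like frame);
no geographic CRS handling exists, which keeps areas (shoelace / 10⁶ →
km²) and containment exact. Conventions, chosen for determinism:

* Boundary points count as inside (shapely `intersects`, equivalent to
  even-odd ray casting with an inclusive boundary for valid rings).
* A point in overlapping zones goes to the zone earliest in file order.
* Zonal means use cell-centre containment. A sliver zone containing no
  cell centre takes the value of the non-nodata cell centre nearest its
  centroid, so no zone is ever undefined; the fallback is logged with a
  count. Cells equal to the nodata value are masked everywhere.
* Raster resampling is available as optional bilinear upsampling by an
  integer factor (default off — the analysis is scale-free after
  standardization, and no canonical target resolution exists).

## Standardization of negative values

Zonal UHI means can be negative (parks cooler than the reference
surface). Bare max-division would then produce negative "standardized"
scores, violating the [0, 1] contract, so negatives are floored to zero
before dividing by the maximum. The alternative — min-max shifting —
would change the relative spacing of the positive scores; flooring
treats "no excess heat" and "cooler than reference" identically, which
matches the hazard's meaning.

## High-rise (flats) layer

A building footprint is high-rise when **strictly more than** the
threshold (default 10) household points fall within it — buildings with
ten or fewer households are unlikely to be genuinely high-rise, and the
strict inequality is exercised at the boundary in tests. The layer then
counts *households* in kept buildings (a people proxy, the quantity of
interest), attributing each household to a zone by its own point
coordinates so towers straddling a boundary split naturally. The layer
is monotone non-increasing in the threshold.

## Jenks classification

Risk classes come from exact Fisher–Jenks natural breaks: dynamic
programming over the sorted **distinct** values (weighted by
multiplicity) minimising total within-class sum of squared deviations.
Working on distinct values guarantees tied values never split across
classes. Among partitions with equal SSD the reconstruction picks the
earliest feasible class end at every step, i.e. lexicographically
smallest class sizes — a pure tie-break for determinism. Exact DP was
preferred over the common stochastic heuristics because it is
oracle-testable (exhaustive enumeration agrees on every instance with
n ≤ 12, k ≤ 4) and deterministic. k = 5 by default with labels
"very low" … "very high"; k is configurable (1–5 have named label
schemes, larger k falls back to numbered classes).

## Spearman correlation and significance

Spearman's rho is the Pearson correlation of average-ranked values —
the standard tie-corrected formulation. Two-sided p-values use
`t = rho·sqrt((n−2)/(1−rho²))` with n−2 degrees of freedom, adequate in
the hundreds-of-zones regime the method targets; a seed-controlled
permutation test is provided for small n. |rho| = 1 is reported as
p = 0. Correlations are computed on the **raw** layers: ranks are
invariant to the positive rescaling used in standardization, so the
choice is cosmetic, and raw values are the clearer statement. Flags:
`**` for p < 0.01, `*` for p < 0.05. No multiple-testing adjustment is
applied (the matrix is descriptive).

## Household profiling

Zones of a chosen class (default "very high") are selected and their
households tallied by Mosaic type. The reporting filter (count strictly
greater than `min_count`, default 1000) applies to the report only; the
full table is always retained. Shares are reported at two decimals,
full precision kept internally.

## Synthetic city generator

The generator emulates the statistical structure the analysis assumes,
with defaults defining the standard study conditions:

| parameter | default | meaning |
|---|---|---|
| grid_size | 16 | 256 square zones |
| zone_side_m | 500 | zone area 0.25 km² |
| uhi_amplitude_c | 5.0 | Gaussian dome peak (°C); a generator default, chosen as a plausible heatwave-night surface-UHI magnitude, not an observed value |
| uhi_sigma_m | 2000 | dome spatial scale |
| uhi_noise_sd_c | 0.3 | additive cell noise |
| uhi centre | 0.4·extent | urban cores rarely sit at the study-area centroid; the offset keeps centre-vs-centroid comparisons meaningful |
| persons_per_household | 2.4 | implied persons = households × 2.4 |
| min/mean zone persons | 1000 / 1500 | UK small-area design targets |
| density_decay_m | 3000 | e-folding of household intensity with distance |
| elderly/ill share max, slope | 0.35, 6 | logistic shares in scaled distance; elderly rise outward, ill rise inward |
| towers | 2 clusters × 4 towers × 30 HH | centre cluster houses type 64, inner ring type 47; every tower passes the >10 filter by construction |

Zone household counts are Poisson draws around a radially decaying
intensity, floored at the minimum-population target; the intensity
scale is calibrated by root-finding so the *floored* expectation hits
the mean target exactly. Positions are uniform within zones; all
randomness flows through one numpy Generator in a fixed draw order
(raster noise, counts, positions, types, low-rise picks), so identical
config + seed gives byte-identical outputs. An optional vertex-jitter
mode produces irregular (still space-filling) zone polygons.

What the generator does **not** emulate: irregular real-world zone
geometries and area variance (real small-area zones vary ~100× in
area), spatial autocorrelation beyond the radial trends, mixed-type
buildings, multi-centre cities, and any physical energy-balance basis
for the UHI. Passing tests therefore demonstrate that the pipeline
recovers structure *of the designed kind*; they say nothing about
retrieval accuracy on real satellite or segmentation data.

The demographic–heat coupling slopes have no empirical anchor; they are
free parameters with the documented defaults above, and the recovery
tests check sign patterns, not magnitudes.

## Numerical choices

* Weight groups must sum to 1 within 1e-9.
* File round trips are stable to 1e-9 relative (all numeric output
  written with ≥ 9 significant digits).
* Degenerate inputs fail loudly: all-nonpositive layers, all-nodata
  rasters, zero-area zones, constant vectors in correlation, k larger
  than the number of distinct values. Validation errors exit the CLI
  with code 2, degenerate-data errors with code 3.
* Problem sizes in the test suite and acceptance script (a 16×16-zone
  city, 100 seeds for the stochastic structure checks, 200 instances
  for the Jenks oracle) were chosen so the whole suite runs in a couple
  of minutes on one CPU while keeping the binomial noise on the
  ≥ 95/100 acceptance rates small.

## Known limitations

* No spatial autocorrelation correction (e.g. Moran's I) on the
  correlation matrix; p-values assume exchangeable zones.
* The hazard layer is a pattern, not a temperature forecast; coupling
  to climate projections is out of scope.
* Vulnerability is binary per geodemographic type; within-type
  heterogeneity (affluence, housing quality) is not modelled.
* Verification against health outcomes (mortality, admissions) is not
  part of the package.
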