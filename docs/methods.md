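# Methods

This note documents the models, conventions, and numerical choices behind
`chmstand`, and what its synthetic-stand tests do and do not demonstrate
about real survey data.

## Raster model and CHM generation

Rasters are single-band planar grids of heights in meters: north-up, row 0
northmost, 0-based indices, cell-center coordinates, half-open cell
intervals `[x, x + cell_size)`. Missing cells are NaN in memory and the
sentinel −9999 on disk (ESRI ASCII grid). No geodetic CRS handling is
attempted; coordinates are planar meters.

Point clouds are rasterized by **max binning**: each cell takes the maximum
z of its points, which approximates the first-return canopy surface of a
dense photogrammetric or LiDAR cloud. Empty cells are filled by the
iterated mean of their valid 8-neighbors. This is a deliberate
simplification of natural-neighbor interpolation: it is dependency-free,
idempotent on void-free rasters, and converges quickly on the small voids
left by dense clouds, but it will smear across large gaps (e.g. occluded
slopes), where a proper interpolator should be applied upstream.

`CHM = DSM − DTM`, clamped below at 0: photogrammetric surfaces can dip
under the terrain model, and negative canopy heights are not physical. A
DTM on the same cell size but a shifted origin is aligned to the DSM grid
by bilinear resampling; differing cell sizes are an error rather than a
silent cross-resolution resample, because the choice of resampling kernel
then materially affects treetop geometry.

## Smoothing

Three averaging filters, all via normalized convolution so nodata cells are
excluded from every average and stay nodata, and windows shrink at raster
edges instead of padding with invented values (stand edges are exactly
where spurious values would create false treetops):

- **lowpass** — mean over a circular neighborhood (cells whose centers lie
  within the radius), the GIS convention for the term;
- **mean** — arithmetic mean over an odd square window;
- **gaussian** — normalized Gaussian kernel truncated at 3σ.

Radii and sigmas are meters by default and converted to cells via the cell
size; cell units are also accepted. Lowpass and mean differ only in
neighborhood shape. All three are exercised against an O(n²k²) brute-force
reference in the tests (tolerance 1e−9).

## Treetop detection

A cell is a treetop iff its height ≥ `min_height` (default 1.37 m, breast
height) and it is strictly greater than every other valid cell in its
neighborhood — circular radius in meters or fixed odd square window in
cells. Plateaus would otherwise yield either zero or many detections; the
tie-break keeps only the plateau cell with the smallest (row, col), so a
flat top produces exactly one treetop, deterministically. Treetop counts
are non-increasing in the search radius and window size, a property the
tests assert on full synthetic stands.

## Crown delineation

Voronoi assignment in cell space: every valid cell is a candidate for its
nearest treetop. A cell is retained in crown *i* iff `chm ≥ exclusion·H_i`
and its distance to the seed is ≤ `maxcrown·H_i`, where `H_i` is the seed's
CHM height (defaults: exclusion 0.7, maxcrown 0.4). Retained cells are then
pruned to the 8-connected component containing the seed, since physical
crowns are contiguous and the height test alone can admit detached
fragments under a neighboring tree. Area is the cell count times the cell
area; perimeter is the rasterized outline (total exposed cell-edge length),
which is biased high relative to smoothed hand-digitized boundaries — a
known property of the estimator, not an error. Externally digitized crown
polygons (GeoJSON with a `tree_id` property) can be supplied to the
regression stage in place of the automatic areas.

## Detection scoring

Matching is **optimal one-to-one assignment**: among pairings with all pair
distances within the threshold (by convention the detection search radius),
the maximum-cardinality, minimum-total-distance matching is chosen via the
Hungarian algorithm on a penalized cost matrix. Nearest-first greedy
acceptance was considered and rejected: it can sacrifice a feasible match
to a locally closer pair (on clustered instances it loses cardinality
roughly a quarter of the time), whereas the assignment solution is optimal
and equally deterministic; the tests verify it against an exhaustive
enumeration oracle on small instances. Unmatched detections are FP,
unmatched field trees FN. TN is reported as 0: on a continuous surface
there is no countable unit of correctly-empty space, and TN enters none of
the scores. Precision, recall, and F are computed at full precision and
rounded to 2 dp only for display.

## Allometry

- Basal area: `π/4·(DBH/100)²` (DBH in cm, area in m²).
- Stem volume: pluggable; the default is the classical form-factor model
  `V = f·BA·H` with `f = 0.36`, chosen so that trees at the calibration
  stand's mean dimensions (35.2 m, 60.94 cm) yield volumes on the scale of
  its mean stem volume (≈3.7–3.8 m³). This is a stand-in for regional
  yield-table volumes, which are proprietary; any species-specific function
  can be registered by name.
- Carbon: the growing-stock inventory form `CST = V·D·BEF·(1+R)·CF`,
  defaults `D = 0.404` t d.m. m⁻³, `BEF = 1.15`, `R = 0.29`, `CF = 0.51`
  MgC (t d.m.)⁻¹ — the Japanese inventory coefficients for larch. The
  equation is linear in V, so per-tree and per-stand aggregation commute,
  which the tests assert.

## Regression models

Candidate predictors per tree: CHM height at the detected apex, crown area
(automatic or manual), crown perimeter, and nearest-neighbor distance.
Predictors with VIF > 5 are removed iteratively (largest first; exact
collinearity is treated as infinite VIF). Model selection is bidirectional
stepwise search minimizing `AIC = n·ln(RSS/n) + 2(p+1)` (Gaussian profile
likelihood; intercept always included), starting from the full post-VIF
model; candidate models with `n ≤ p+1` are skipped. RSS is floored at the
machine-noise scale of the response so numerically exact fits are compared
by the penalty term alone rather than by rounding noise. Accuracy is
`RMSE = √(SS_res/n)` and `R² = 1 − SS_res/SS_tot`; LOOCV refits n times and
scores held-out predictions with the same formulas, R² against the
full-sample mean. Note that AIC stepwise admits a pure-noise candidate with
probability ≈ P(χ²₁ > 2) ≈ 0.16 per candidate; this is a property of the
criterion, not a defect, and the intercept-only and recovery tests are
calibrated to it.

## Synthetic stands

The generator emulates a single-species old conifer plantation:

| parameter | default | rationale |
|---|---|---|
| stand | 96.478 m square (0.9308 ha) | calibration stand area |
| density | 147 stems ha⁻¹ | old plantation after a century of self-thinning |
| min spacing | 3 m | hardcore distance implied by that density |
| height | N(35.2, 3.27²) truncated to [25.8, 42.9] m | calibration stand moments |
| DBH | N(60.94, 7.14²) cm, corr(H, DBH) = 0.7 | linear-in-height with Gaussian residual |
| crown area | lognormal, mean 56.65 m², SD 21.27 m² | moment-matched |
| crown profile | z(r) = H·(1 − (r/R)^a), a = 2 | rounded conifer crown |
| terrain | planar ramp, 19° | mid-range of the site's 18–20° slope |
| cells / points | 0.5 m; 40 pts m⁻² | survey-scale raster and dense cloud |
| surface noise | 0.05 m SD (0 for recovery tests) | photogrammetric roughness |

Tree count is Poisson(density × area); placement is sequential rejection
under the hardcore constraint, failing loudly if infeasible. One integer
seed drives a single RNG stream in a fixed order (count, positions,
heights, DBH residuals, crown areas, then surface and point noise), so
identical configurations are byte-identical.

What the generator does **not** emulate: crown asymmetry and interlocking,
within-crown texture, occlusion and SfM reconstruction artifacts, stem
lean, understorey, and multi-species mixtures. Passing recovery tests
therefore demonstrate the pipeline's correctness and discretization
behavior, not field-accuracy on real imagery — on real old-growth canopies
detection and height accuracy are lower, dominated by crown overlap and
surface reconstruction error, not by the algorithmic properties tested
here.

## Numerical choices and degenerate inputs

- Height-extraction error on synthetic stands is bounded by the crown
  profile's discretization: `|err| ≤ H·(d/R)^a + tan(slope)·d` with `d` the
  half-cell diagonal (0.354 m at 0.5 m cells). At the defaults this is
  under 0.5 m for crowns with R ≥ ~3.4 m; smaller crowns can exceed it, so
  per-tree bounds, not a flat figure, are the tested guarantee.
- At exclusion e the retained crown disc of the profile has area
  `πR²·(1 − e^(2/a))` — half of πR² at a = 2, e = 0.5 — which is the
  expectation recovery tests check against.
- F-score with TP = 0: 0 when any detection or field tree exists, NaN
  (explicitly not-a-value) when TP = FP = FN = 0.
- All-nodata rasters, empty point clouds, non-overlapping clip polygons,
  treetops on nodata cells, and single-tree nearest-distance queries raise
  errors naming the offending input; nothing is silently coerced.
- Problem sizes in tests and the acceptance script (a 0.93 ha stand at
  0.5 m cells, ~193² rasters, 50-seed regression ensembles) were chosen as
  the smallest sizes at which the stand-level statistics are stable.

## Known limitations

- Lowpass/mean/Gaussian semantics follow GIS conventions; other toolchains'
  "lowpass" kernels may differ, so cross-software comparisons should match
  kernels, not labels.
- The Voronoi crown algorithm assigns by seed distance, not by CHM
  watershed geometry; interlocking crowns of unequal size are split at the
  bisector, biasing large crowns low and small crowns high.
- The form-factor volume default is a generic conifer stand-in; serious
  volume work should register a regional yield-table function.
- LOOCV is exact refitting (O(n) OLS fits); fine at inventory-plot n,
  not meant for thousands of trees.
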