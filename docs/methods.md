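# Methods

## Scope and data model

`urbanmosaic` turns collections of tagged geographic features — each a
polygon or line with a flat map of lowercase key→value attributes in the
OpenStreetMap vocabulary — into a categorical land-cover raster, derives an
urbanization index from it, and uses that index as a site covariate in
multi-season occupancy models. All processing happens in a single projected
CRS with meter units; geographic (degree) inputs are rejected with an
explanatory error rather than reprojected, because the buffering rules are
expressed in meters. GeoJSON files therefore carry a declared projected CRS
(a legacy `crs` member or a caller-supplied identifier) — a deliberate,
documented deviation from RFC 7946, which mandates WGS84.

Rasters use the north-up convention: `transform = (x0, y0, s)` places the
upper-left corner of cell (0, 0) at (x0, y0); cell (row, col) covers the
half-open square `[x0+col·s, x0+(col+1)·s) × (y0−(row+1)·s, y0−row·s]`.
The nodata code is fixed at 0; framework class codes run 1–28. GeoTIFF I/O
uses the standard georeferencing tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA) with the CRS identifier and legend carried as JSON in the
image description, giving lossless round trips.

## Classification registry

The 27 classes fall into three categories. Land use (1–6: residential,
commercial, industrial, institutional, recreational, cemetery) captures
human activity by type. Green cover (7–13) splits vegetation by density and
management — protected/unknown vegetation (7), forest (8), low vegetation
(9), open green (10) — plus barren soil (11), water (12) and wetland (13).
Infrastructure (14–27) holds buildings (14), parking (15), roads by type
and hence hypothetical traffic load (motorway 16, unknown-type 17, primary
18, secondary 19, tertiary 20, residential 21, service 22), hiking paths
(23), railways (24), fences (25), linear features under construction or
abandoned (26), and airstrips (27). Code 28, "developed unknown", is
reserved for cells a global map labels built/developed without any
tagged-feature detail. Codes 7, 17 and 28 are exactly the classes whose
sub-categorization is unknown, and their area shares are reported by the
completeness diagnostics.

The shipped tag lists are a documented default reconstruction, not a
canonical standard: the registry serializes to YAML precisely so users can
substitute their own key→value tables, lane means and priority ranks.
Matching is case-insensitive on both sides; a feature joins **every** class
whose predicates it satisfies (multi-membership), because overlaps are
resolved later by raster priority, not by vector precedence.

### Line buffering

Linear features become flat-capped polygons of total width
`lanes × 6 m`, with `lanes` read from the feature's `lanes` tag when it
parses as a positive number and imputed from the road type's mean otherwise
(motorway 4, primary 3, secondary/tertiary/residential/unknown 2, service
1). Fixed widths override the lane rule for non-road lines: paths 2 m,
railways 6 m, fences 1 m, airstrips 30 m. The `lanes` value is treated as
the total for the carriageway (no per-direction splitting), matching the
single per-lane constant.

## Rasterization, priority merge, integration

A cell takes a class iff its **center** lies strictly inside some polygon
of that class's layer. At 30 m cells this means roads narrower than the
cell can miss centers entirely; the synthetic-city fixtures are constructed
so that this behaviour is exact and testable rather than incidental.

The merge paints masks in ascending priority, so the highest-ranked class
coding a cell wins. The default order (lowest to highest): land-use classes,
developed-unknown, vegetation green cover, barren, water, buildings,
parking, roads by ascending traffic load (service → motorway), airstrip,
construction-linear, then hiking paths, railways and fences above all —
the last three run uninterrupted across landscapes and act as movement
corridors or barriers, so they must survive the overlay. Features tagged
`bridge`/`tunnel` can be excluded from rasterization (`exclude_elevated`),
a declared stand-in for true 3-D layering: the segment then does not
overwrite the layer beneath it.

Tiled merging (`tile_and_merge`) exists for bounded-memory processing of
large areas and is bit-identical to the untiled merge because the priority
rule is purely cell-local; this equivalence is asserted over random stacks
and tile sizes, including non-divisors.

Integration backfills every void cell from the reclassified global raster
(nearest-neighbor aligned if on a different grid — interpolation is
meaningless for class codes); global built/developed codes map to class 28.

## Validation metrics

* **Completeness** = 1 − (void cells)/(total cells) of the feature-only
  raster; per class, the absolute area difference against the global layer
  is reported along with a normalized ratio min(1, area_osm/area_global)
  for cross-study comparability (both emitted, clearly labelled).
* **Urban proportion** = area under land-use + infrastructure categories
  (including class 28) over total area.
* **Accuracy**: stratified random cells (uniform without replacement within
  class, reproducible under seed) against reference labels. The confusion
  matrix fixes predicted-on-rows, reference-on-columns, so per-class
  precision is the row-normalized diagonal TP/(TP+FP) — classes never
  predicted are reported as missing, not zero. Cohen's
  κ = (p_o − p_e)/(1 − p_e) with the convention κ = 1 when p_o = p_e = 1
  (degenerate single-class case). Both metrics are implemented directly
  from the formulas; the test suite cross-checks κ against an independent
  library implementation and a brute-force oracle.
* **Paired-area regression**: OLS `y = a + b·x` between per-study-area
  totals (e.g. building surface from two layers), reporting slope,
  intercept and R²; a constant response returns slope 0 and R² 0, constant
  x is an error.

## Urbanization index

Per 30 m cell:

```
raw = w_v · (3·P_forest + 2·P_lowveg + 1·P_open)/6
    + w_b · P_building
    + w_r · (1 − D̂_road)
    + w_w · (1 − D̂_water)
```

`P` are focal proportions: block aggregation at factor `window/cell` (900 m
for vegetation, 450 m for buildings) followed by block-constant
disaggregation, so values are exact block fractions in [0, 1]; edge blocks
use their actual cell counts. `D̂` are Euclidean distance transforms
(cell-center to nearest target center, exact via the standard EDT) min-max
normalized to [0, 1]; road targets default to primary/secondary/motorway
plus railways, water to the water class.

The vegetation-internal 3:2:1 weighting (forest : low vegetation : open
green) reflects relative shelter value. The component weights and signs are
configuration with defaults w_v = −1, w_b = +1, w_r = +0.5, w_w = −0.25:
vegetation and water proximity pull toward "less urban", buildings and road
proximity toward "more urban". These four numbers are a declared design
choice — only the 3:2:1 ratio, the window sizes and the 0–1 distance
normalization are externally fixed — and every weight is user-overridable;
the test suite asserts the monotonicity contract (index non-decreasing in
building proportion, non-increasing in vegetation proportions under the
default signs), not the default numbers. The final affine `output_scale`
defaults to mapping the theoretical extremes of the configured weights to
[0, 100] and is presentation only.

A note on windows: the focal windows are side lengths (900 m and 450 m),
i.e. aggregation factors 30 and 15 on the 30 m grid.

## Autologistic occupancy model

For site i with standardized covariate x_i, latent occupancy z_t ∈ {0, 1}:

* ψ₁ = logit⁻¹(β₀ + β₁x_i) — the first season has no autologistic term
  (there is no prior state);
* ψ_t = logit⁻¹(β₀ + β₁x_i + θ·z_{t−1}) for t > 1;
* weekly detections y ~ Bernoulli(p·z_t) with p = logit⁻¹(α), detection
  intercept-only by default (the design admits per-week covariates);
  unsampled weeks are missing-at-random and skipped.

The marginal likelihood sums over latent states with a two-state forward
recursion per site (probability scale; seasons are few, underflow is not a
concern), making it exact — the test suite pins it against exhaustive
enumeration over all latent configurations at tolerance 1e-10, and against
the independent-season factorization at θ = 0.

Fitting is quasi-Newton (L-BFGS-B) from five documented starts: the zero
vector plus four seeded ±1-scaled perturbations; the best finite optimum is
kept. Standard errors come from the observed information (central-difference
Hessian at the optimum, step 1e-4); `converged` honestly reports optimizer
success and a positive-definite information check. AIC = −2ℓ + 2K with
K = 4 (covariate model) or 3 (null). Model competition reports ΔAIC,
Akaike weights exp(−ΔAIC/2)/Σ, cumulative weight down the ranking, and a
competitive flag at ΔAIC ≤ 2. Fitting a single season is refused: θ is not
identified without a season-to-season transition.

**Equilibrium occupancy ratio.** To compare the least and most urban sites,
occupancy is evaluated at the stationary point of the chain's marginal
recursion ψ ← (1−ψ)·logit⁻¹(η) + ψ·logit⁻¹(η+θ), solved by damped
iteration to 1e-10. This fixed point is the long-run occupancy a forward
simulation converges to (and reduces to the closed form logit⁻¹(η) at
θ = 0); the ratio is ψ*(x_high)/ψ*(x_low). Which season's occupancy such
ratios should refer to is genuinely open — the stationary value is this
package's declared choice.

## Synthetic data: what it emulates and what it does not

`generate_city` lays out a gridded city: orthogonal roads every 600 m
cycling through types with per-type lane means, with every third road
omitting its `lanes` tag and one road carrying an unparseable value
(exercising imputation); land-use and green-cover blocks cycling through
all polygon classes, some blocks deliberately untagged (planting voids for
the integration step); seeded axis-aligned buildings; a parking lot; water;
and one linear feature for each remaining line rule. Every registry rule is
exercised by at least one feature.

The ground truth raster is computed by direct coordinate arithmetic —
rectangle containment tests at cell centers, painted in priority order — in
a code path sharing only the recipe's placement constants and the priority
table with the geometric pipeline, not a single routine. All edges are
placed off the cell-center lattice (centers sit at coordinates ≡ 15 mod
30 m), so the cell-center rule has no ties and the pipeline/ground-truth
comparison is exact, cell for cell.

What the fixtures do **not** emulate: curved or dead-end streets, real
street-network topology, multipolygons with holes, overlapping tag
semantics, contributor noise and tag misspellings, and bridges beyond the
exclusion-flag mechanism. Passing the end-to-end equivalence therefore
shows the geometric and priority machinery is correct, not that the default
tag registry matches any particular city's mapping culture.

`generate_global_lulc` produces a smoothed random multi-class raster whose
built class occupies exactly the requested quantile of a core-centered
score. `simulate_detections` draws from the occupancy model itself, with
default conditions emulating a four-season urban camera grid: 93 sites,
unequal effort of 7/5/5/1 weeks per season (median 5), β = (−0.5, 0.8),
θ = 1, α = 0.5.

## Problem sizes and numerical choices

The end-to-end city is 200×200 cells (6×6 km at 30 m) with ~500 features.
The parameter-recovery study in the test suite runs 200 replicates at 100
sites × 4 seasons × 6 weeks; `scripts/acceptance.py` uses 80 replicates for
its coverage/preference quantities — at ~0.1 s per pair of fits both sizes
are comfortable, and 80 replicates already bound the coverage estimate's
Monte-Carlo error near ±5 points. Invalid input geometries are repaired
with `make_valid` (polygonal parts kept) and dropped with a warning if
still invalid; zero-length lines are dropped; degenerate normalizations
(constant raster, constant covariate, zero-variance regressors) raise
errors naming the problem rather than returning NaN.

## Known limitations

* No reprojection: inputs must already share one projected CRS.
* No true 3-D stacking of infrastructure; the bridge/tunnel exclusion flag
  is a stated simplification.
* Detection is intercept-only by default; site-level spatial
  autocorrelation between camera sites is not modeled.
* The default registry is a reconstruction; users with authoritative class
  tables should load them via YAML.
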