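# urbanmosaic

Urban areas are among the most heterogeneous landscapes on Earth, yet global
land-cover maps collapse them into a single "built" class. `urbanmosaic`
rebuilds that lost heterogeneity from community-mapped geographic features —
polygons and lines carrying key→value tags such as `landuse=residential`,
`highway=primary`, `lanes=2` — and carries the result all the way into
wildlife statistics:

1. **Classify** tagged features into 27 urban land-cover classes in three
   categories (human land use, green cover, infrastructure) via an editable
   rule registry; convert linear features to polygons with per-road-type
   buffers (6 m per lane, lanes imputed from the type's mean when the tag is
   missing or unparseable).
2. **Rasterize and merge** the class layers onto a 30 m grid under a
   priority table (land use < green cover < buildings < roads by traffic
   load < paths/railways/fences), using the cell-center rule.
3. **Integrate** the result into a coarse global land-cover raster: any cell
   without tagged-feature information takes the (reclassified) global class,
   with built/developed cells lacking detail becoming class 28, "developed
   unknown".
4. **Validate**: completeness (1 − void-cell fraction), per-class area
   differences, urban proportion, stratified accuracy with Cohen's κ and
   per-class precision (row-normalized confusion-matrix diagonal), and
   paired-area OLS regression between layers.
5. **Urbanization index**: an arithmetic weighted sum per 30 m cell of focal
   vegetation proportions in 900 m blocks (weighted 3:2:1 for forest :
   low vegetation : open green), focal building proportion in 450 m blocks,
   and 0–1-normalized Euclidean distances to major roads/railways and to
   water; scaled to [0, 100], larger = more urban.
6. **Occupancy**: autologistic multi-season occupancy models fit by exact
   maximum likelihood. Latent occupancy follows
   ψ₁ = logit⁻¹(x′β), ψ_t = logit⁻¹(x′β + θ·z_{t−1}) for t > 1, with weekly
   detections Bernoulli(p·z_t), p = logit⁻¹(α); models are compared by AIC
   (ΔAIC, Akaike weights, competitive ≤ 2 ΔAIC).

A first-class synthetic-data module generates a tagged city with an
analytically known ground-truth raster, a blobby global land-cover raster,
and detection histories simulated from the occupancy model, so the entire
pipeline is testable offline.

## Worked example

```python
from urbanmosaic import *
from urbanmosaic.fixtures import *
from urbanmosaic.occupancy import SiteCovariates

fx  = generate_city(CityRecipe(seed=1))
reg = default_registry()
osm = build_lulc(fx.polygons, fx.lines, reg, fx.grid)
glob = reclass_global(generate_global_lulc(seed=2, crs=fx.recipe.crs),
                      default_reclass_map())
full = integrate(osm, glob)
rep  = completeness(osm, glob, reg)
idx  = urbanization_index(full)

h, x = simulate_detections(OccSimRecipe(seed=3))
cov  = SiteCovariates(x=(x - x.mean()) / x.std(), raw_mean=x)
fits = {"null":      fit_autologistic(h, cov, "null", seed=0),
        "covariate": fit_autologistic(h, cov, "covariate", seed=0)}
print(compare_aic(fits))
```

Output (trimmed):

```
cells: 40000 void: 1910
completeness: 0.952  urban proportion: 0.641
index range: 40.4 - 63.0
    model         AIC      dAIC       weight  competitive
covariate 1335.876100  0.000000 1.000000e+00         True
     null 1377.699813 41.823713 8.281253e-10        False
beta1 = 1.00 +/- 0.17, theta = 1.25
occupancy ratio (most vs least urban site): 23.01
```

Reading: the tagged features alone explain 95.2% of the study area (1,910
of 40,000 cells needed global backfill); 64.1% of the area is developed
surface. The occupancy model with the urbanization index beats the null by
41.8 AIC units and estimates a strong positive covariate effect (β₁ = 1.00
on the standardized index) with between-season persistence θ = 1.25;
equilibrium occupancy at the most urban site is ~23× that at the least
urban one. (The detection histories here were simulated with a positive
effect, so this is the expected recovery.)

## Command line

```bash
urbanmosaic simulate city   --seed 1 --out data/
urbanmosaic simulate global --seed 1 --out data/
urbanmosaic run --polygons data/city_polygons.geojson \
    --lines data/city_lines.geojson --global-raster data/global_lulc.tif \
    --bbox 0 0 6000 6000 --crs synthetic-city-meters --out run/
```

Each stage writes its artifact plus `manifest.json` (inputs, config hash,
seed, version); deterministic stages re-run bit-identically.

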