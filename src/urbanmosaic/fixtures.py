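"""Synthetic study systems with known ground truth.

Three generators make every other module testable without any download:

* :func:`generate_city` — a gridded synthetic city of tagged features
  (roads with partly missing ``lanes`` tags, buildings, land-use blocks,
  green/water patches, and one feature per registry rule) together with a
  ground-truth class raster computed by direct coordinate arithmetic, in
  a code path deliberately disjoint from the classify/buffer/rasterize
  pipeline: the two share the recipe's placement constants and the
  priority table, but not a single geometric routine, so end-to-end
  agreement is evidence rather than tautology.
* :func:`generate_global_lulc` — a blobby coarse land-cover raster with a
  built-up core, standing in for a satellite-derived global map.
* :func:`simulate_detections` — detection histories drawn from the
  autologistic occupancy model itself.

All geometry is axis-aligned and all edges are placed off the 30 m
cell-center lattice (centers sit at coordinates congruent to 15 mod 30;
edges are kept off that residue), so the cell-center rasterization rule
has no ties and ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, box

from .features import TaggedFeature, TaggedFeatureCollection
from .occupancy import DetectionHistory, AutoOccParams
from .raster import CategoricalRaster, GridSpec
from .registry import ClassRegistry, default_registry
from .overlay import ReclassMap

__all__ = [
    "CityRecipe",
    "CityFixture",
    "OccSimRecipe",
    "generate_city",
    "generate_global_lulc",
    "default_global_legend",
    "default_reclass_map",
    "simulate_detections",
]

CELL = 30.0

# block land-cover cycle: mixes urban land use, green cover and planted
# voids (None = no tagged feature, exercising global-map backfill)
_BLOCK_CYCLE = [
    "residential", "commercial", "forest", "residential", "industrial",
    "open_green", "residential", "institutional", "low_vegetation",
    "residential", "recreational", None, "commercial", "cemetery",
    "protected_unknown_vegetation", "residential", "wetland", "barren",
]

_BLOCK_TAGS = {
    "residential": {"landuse": "residential"},
    "commercial": {"landuse": "commercial"},
    "industrial": {"landuse": "industrial"},
    "institutional": {"amenity": "school"},
    "recreational": {"leisure": "golf_course"},
    "cemetery": {"landuse": "cemetery"},
    "forest": {"landuse": "forest"},
    "low_vegetation": {"natural": "scrub"},
    "open_green": {"leisure": "park"},
    "protected_unknown_vegetation": {"boundary": "protected_area"},
    "wetland": {"natural": "wetland"},
    "barren": {"natural": "sand"},
}

_BLOCK_CODE = {
    "residential": 1, "commercial": 2, "industrial": 3, "institutional": 4,
    "recreational": 5, "cemetery": 6, "protected_unknown_vegetation": 7,
    "forest": 8, "low_vegetation": 9, "open_green": 10, "barren": 11,
    "wetland": 13,
}

# road-type cycle along the grid, with per-type mean lanes
_ROAD_CYCLE = ["primary", "secondary", "residential", "tertiary", "residential", "service"]
_ROAD_TAG = {
    "primary": ("highway", "primary", 18),
    "secondary": ("highway", "secondary", 19),
    "tertiary": ("highway", "tertiary", 20),
    "residential": ("highway", "residential", 21),
    "service": ("highway", "service", 22),
}


@dataclass
class CityRecipe:
    """Layout constants for the synthetic city."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 6000.0, 6000.0)
    road_grid_spacing: float = 600.0
    lane_table: dict[str, float] = field(
        default_factory=lambda: {
            "primary": 3, "secondary": 2, "tertiary": 2, "residential": 2, "service": 1
        }
    )
    building_density: float = 0.5
    water: tuple[float, float, float, float] | None = (4206.0, 4206.0, 5394.0, 5394.0)
    crs: str = "synthetic-city-meters"

    def __post_init__(self):
        if not 0.0 <= self.building_density <= 1.0:
            raise ValueError("building_density must be in [0, 1]")
        # road strips must fit between centerlines
        max_width = 6.0 * max(self.lane_table.values())
        if self.road_grid_spacing <= 2 * max_width:
            raise ValueError("road_grid_spacing too small for the widest road")


@dataclass
class CityFixture:
    polygons: TaggedFeatureCollection
    lines: TaggedFeatureCollection
    ground_truth: CategoricalRaster
    grid: GridSpec
    recipe: CityRecipe


@dataclass
class OccSimRecipe:
    """Conditions for simulating camera-trap detection histories.

    Defaults emulate the study conditions of a four-season urban camera
    grid: 93 sites, weekly sampling with unequal effort across seasons
    (1-7 weeks, median 5), and a moderate positive covariate effect.
    """

    seed: int = 0
    n_sites: int = 93
    n_seasons: int = 4
    weeks_per_season: tuple[int, ...] = (7, 5, 5, 1)
    true_params: AutoOccParams = field(
        default_factory=lambda: AutoOccParams(beta=np.array([-0.5, 0.8]), theta=1.0, alpha=np.array([0.5]))
    )
    covariate_values: np.ndarray | None = None

    def __post_init__(self):
        if self.n_sites < 2 or self.n_seasons < 1:
            raise ValueError("need n_sites >= 2 and n_seasons >= 1")
        if len(self.weeks_per_season) != self.n_seasons:
            raise ValueError("weeks_per_season length must equal n_seasons")


# ---------------------------------------------------------------------------
# synthetic city
# ---------------------------------------------------------------------------

def _centerlines(recipe: CityRecipe) -> list[float]:
    xmin, _, xmax, _ = recipe.extent
    first = xmin + recipe.road_grid_spacing / 2.0 + CELL / 2.0
    return [c for c in np.arange(first, xmax, recipe.road_grid_spacing)]


def _blocks(recipe: CityRecipe):
    """Block rectangles inset 3 m from road centerlines, with cycle type."""
    xmin, ymin, xmax, ymax = recipe.extent
    lines = _centerlines(recipe)
    xs = [xmin] + lines + [xmax]
    ys = [ymin] + lines + [ymax]
    out = []
    k = 0
    for i in range(len(ys) - 1):
        for j in range(len(xs) - 1):
            x0 = xs[j] + (3.0 if j > 0 else 0.0)
            x1 = xs[j + 1] - (3.0 if j + 1 < len(xs) - 1 else 0.0)
            y0 = ys[i] + (3.0 if i > 0 else 0.0)
            y1 = ys[i + 1] - (3.0 if i + 1 < len(ys) - 1 else 0.0)
            out.append((_BLOCK_CYCLE[k % len(_BLOCK_CYCLE)], (x0, y0, x1, y1)))
            k += 1
    return out


def _roads(recipe: CityRecipe):
    """Road centerlines with type, lanes-tag behaviour and true width.

    Every third road omits its ``lanes`` tag (imputed from the type's
    mean) and one road carries an unparseable tag, exercising the
    fallback; the analytic width mirrors exactly the imputation the
    classifier documents.
    """
    xmin, ymin, xmax, ymax = recipe.extent
    lines = _centerlines(recipe)
    roads = []
    k = 0
    for orient in ("v", "h"):
        for c in lines:
            rtype = _ROAD_CYCLE[k % len(_ROAD_CYCLE)]
            mean_lanes = recipe.lane_table[rtype]
            tags = dict([_ROAD_TAG[rtype][:2]])
            if k % 3 == 2:
                true_lanes = mean_lanes          # tag omitted -> imputed
            elif k == 1:
                tags["lanes"] = "two"            # unparseable -> imputed
                true_lanes = mean_lanes
            else:
                true_lanes = mean_lanes + (1 if k % 4 == 0 else 0)
                tags["lanes"] = str(int(true_lanes))
            width = 6.0 * true_lanes
            code = _ROAD_TAG[rtype][2]
            if orient == "v":
                geom = ((c, ymin), (c, ymax))
                rect = (c - width / 2, ymin, c + width / 2, ymax)
            else:
                geom = ((xmin, c), (xmax, c))
                rect = (xmin, c - width / 2, xmax, c + width / 2)
            roads.append({"id": f"road{k}", "tags": tags, "code": code, "geom": geom, "rect": rect})
            k += 1
    return roads


def _special_lines(recipe: CityRecipe):
    """One linear feature per remaining line rule, off the road lattice."""
    xmin, ymin, xmax, ymax = recipe.extent
    span_x = lambda y: ((xmin, y), (xmax, y))
    span_y = lambda x: ((x, ymin), (x, ymax))
    items = [
        ("rail0", {"railway": "rail"}, 24, "h", 2145.0, 6.0),
        ("path0", {"highway": "path"}, 23, "h", 1245.0, 2.0),
        ("fence0", {"barrier": "fence"}, 25, "h", 3465.0, 1.0),
        ("constr0", {"highway": "construction"}, 26, "h", 4665.0 - 600.0, 12.0),
        ("unclass0", {"highway": "road"}, 17, "h", 4665.0, 12.0),
        ("mway0", {"highway": "motorway"}, 16, "v", 5415.0, 24.0),
        ("runway0", {"aeroway": "runway"}, 27, "v", 2445.0, 30.0),
    ]
    out = []
    for fid, tags, code, orient, c, width in items:
        if orient == "h":
            geom = span_x(c)
            rect = (xmin, c - width / 2, xmax, c + width / 2)
        else:
            geom = span_y(c)
            rect = (c - width / 2, ymin, c + width / 2, ymax)
        out.append({"id": fid, "tags": tags, "code": code, "geom": geom, "rect": rect})
    return out


def _buildings(recipe: CityRecipe, blocks, rng):
    """Axis-aligned buildings inside urban land-use blocks.

    Corner coordinates are even integers (cell centers are odd multiples
    of 15), so no edge can pass through a cell center.
    """
    out = []
    if recipe.building_density == 0:
        return out
    n_per_block = int(round(recipe.building_density * 12))
    bid = 0
    for btype, (x0, y0, x1, y1) in blocks:
        if btype not in ("residential", "commercial", "industrial", "institutional"):
            continue
        w, h = x1 - x0, y1 - y0
        if w < 80 or h < 80:
            continue
        for _ in range(n_per_block):
            size = 2.0 * rng.integers(10, 15)  # 20-28 m, even
            bx = x0 + 2.0 * rng.integers(3, int((w - size - 6) // 2))
            by = y0 + 2.0 * rng.integers(3, int((h - size - 6) // 2))
            out.append((f"bld{bid}", (bx, by, bx + size, by + size)))
            bid += 1
    return out


def _parking(blocks):
    """One parking lot in the first commercial block."""
    for btype, (x0, y0, x1, y1) in blocks:
        if btype == "commercial" and x1 - x0 > 200:
            return ("park_lot0", (x1 - 124.0, y0 + 6.0, x1 - 4.0, y0 + 96.0))
    return None


def generate_city(recipe: CityRecipe | None = None, registry: ClassRegistry | None = None) -> CityFixture:
    """Generate the tagged-feature city and its analytic ground truth."""
    recipe = recipe or CityRecipe()
    reg = registry or default_registry()
    rng = np.random.default_rng(recipe.seed)
    xmin, ymin, xmax, ymax = recipe.extent
    grid = GridSpec(recipe.extent, CELL, recipe.crs)

    blocks = _blocks(recipe)
    roads = _roads(recipe)
    specials = _special_lines(recipe)
    buildings = _buildings(recipe, blocks, rng)
    parking = _parking(blocks)

    # --- tagged feature collections (pipeline input) ----------------------
    polys: list[TaggedFeature] = []
    for i, (btype, rect) in enumerate(blocks):
        if btype is None:
            continue
        polys.append(TaggedFeature(id=f"block{i}", geometry=box(*rect), tags=dict(_BLOCK_TAGS[btype])))
    if recipe.water is not None:
        polys.append(TaggedFeature(id="water0", geometry=box(*recipe.water), tags={"natural": "water"}))
    for bid, rect in buildings:
        polys.append(TaggedFeature(id=bid, geometry=box(*rect), tags={"building": "yes"}))
    if parking is not None:
        pid, rect = parking
        polys.append(TaggedFeature(id=pid, geometry=box(*rect), tags={"amenity": "parking"}))

    lines: list[TaggedFeature] = []
    for r in roads + specials:
        lines.append(TaggedFeature(id=r["id"], geometry=LineString(r["geom"]), tags=dict(r["tags"])))

    fc_polys = TaggedFeatureCollection(features=polys, crs=recipe.crs)
    fc_lines = TaggedFeatureCollection(features=lines, crs=recipe.crs)

    # --- analytic ground truth (independent path) -------------------------
    # every feature as (class_code, rectangle); containment by coordinate
    # comparison, priority by rank-ordered painting
    rects: list[tuple[int, tuple[float, float, float, float]]] = []
    for btype, rect in blocks:
        if btype is not None:
            rects.append((_BLOCK_CODE[btype], rect))
    if recipe.water is not None:
        rects.append((12, recipe.water))
    for _, rect in buildings:
        rects.append((14, rect))
    if parking is not None:
        rects.append((15, parking[1]))
    for r in roads + specials:
        rects.append((r["code"], r["rect"]))

    xs, ys = grid.cell_centers()
    truth = np.zeros(grid.shape, dtype=np.int32)
    for code, (rx0, ry0, rx1, ry1) in sorted(rects, key=lambda cr: reg.priority[cr[0]]):
        inside = (xs > rx0) & (xs < rx1) & (ys > ry0) & (ys < ry1)
        truth[inside] = code
    gt = CategoricalRaster(values=truth, transform=grid.transform, crs=recipe.crs, nodata=0, legend=reg.legend())
    return CityFixture(polygons=fc_polys, lines=fc_lines, ground_truth=gt, grid=grid, recipe=recipe)


# ---------------------------------------------------------------------------
# synthetic global land cover
# ---------------------------------------------------------------------------

def default_global_legend() -> dict[int, str]:
    return {1: "forest", 2: "grassland", 3: "cropland", 4: "water", 5: "barren", 6: "built", 7: "wetland"}


def default_reclass_map() -> ReclassMap:
    """Map the synthetic global legend into framework codes (built -> 28)."""
    return ReclassMap(
        entries={1: 8, 2: 9, 3: 9, 4: 12, 5: 11, 7: 13},
        developed_codes={6},
    )


def generate_global_lulc(
    extent=(0.0, 0.0, 6000.0, 6000.0),
    cell_size: float = CELL,
    seed: int = 0,
    built_fraction: float = 0.3,
    crs: str = "synthetic-city-meters",
    single_class: int | None = None,
) -> CategoricalRaster:
    """Blobby multi-class coarse land cover with a built core.

    The built class occupies exactly the top ``built_fraction`` quantile
    of a smoothed core-centered score, emulating a city footprint; the
    rest is partitioned into the other legend classes by quantiles of a
    second smoothed noise field.
    """
    grid = GridSpec(extent, cell_size, crs)
    legend = default_global_legend()
    if single_class is not None:
        vals = np.full(grid.shape, single_class, dtype=np.int32)
        return CategoricalRaster(values=vals, transform=grid.transform, crs=crs, nodata=0, legend=legend)
    rng = np.random.default_rng(seed)
    nrow, ncol = grid.shape
    rr, cc = np.mgrid[0:nrow, 0:ncol]
    core = -np.hypot(rr - nrow / 2.0, cc - ncol / 2.0)
    score = core + ndimage.gaussian_filter(rng.normal(size=grid.shape), 6) * (nrow / 12.0)
    built = score >= np.quantile(score, 1.0 - built_fraction)
    texture = ndimage.gaussian_filter(rng.normal(size=grid.shape), 8)
    out = np.zeros(grid.shape, dtype=np.int32)
    others = [1, 2, 3, 4, 5, 7]
    t = texture[~built]
    qs = np.quantile(t, np.linspace(0, 1, len(others) + 1))
    lab = np.clip(np.searchsorted(qs, t, side="right") - 1, 0, len(others) - 1)
    fill = np.array(others, dtype=np.int32)[lab]
    out[~built] = fill
    out[built] = 6
    return CategoricalRaster(values=out, transform=grid.transform, crs=crs, nodata=0, legend=legend)


# ---------------------------------------------------------------------------
# detection histories
# ---------------------------------------------------------------------------

def simulate_detections(recipe: OccSimRecipe | None = None) -> tuple[DetectionHistory, np.ndarray]:
    """Draw detection histories from the autologistic occupancy model.

    z_1 ~ Bernoulli(invlogit(x'beta)); z_t ~ Bernoulli(invlogit(x'beta +
    theta*z_{t-1})); weekly y ~ Bernoulli(p*z_t) with p = invlogit(alpha).
    Returns the history and the (unstandardized) covariate values used.
    """
    from scipy.special import expit

    recipe = recipe or OccSimRecipe()
    rng = np.random.default_rng(recipe.seed)
    p = recipe.true_params
    n, T = recipe.n_sites, recipe.n_seasons
    if recipe.covariate_values is not None:
        x = np.asarray(recipe.covariate_values, dtype=float)
        if x.size != n:
            raise ValueError("covariate_values length must equal n_sites")
    else:
        x = rng.normal(size=n)
    eta = p.beta[0] + (p.beta[1] * x if p.beta.size > 1 else 0.0)
    pdet = expit(p.alpha[0])
    max_w = max(recipe.weeks_per_season)
    y = np.full((n, T, max_w), np.nan)
    z = rng.random(n) < expit(eta)
    for t in range(T):
        if t > 0:
            z = rng.random(n) < expit(eta + p.theta * z.astype(float))
        w = recipe.weeks_per_season[t]
        det = (rng.random((n, w)) < pdet) & z[:, None]
        y[:, t, :w] = det.astype(float)
    h = DetectionHistory(
        y=y,
        sites=[f"site{i}" for i in range(n)],
        seasons=[f"season{t+1}" for t in range(T)],
    )
    return h, x
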