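"""Rasterization, priority merge, and global-map integration.

Per-class feature layers are burned onto a common 30 m grid by the
cell-center rule (a cell takes the class iff its center lies inside some
polygon of the layer), merged into one land-cover map under the registry's
priority table (higher rank wins the cell), and finally backfilled from a
reclassified coarse global land-cover raster so no cell is left
uncharacterized — cells the global map calls built/developed but that no
tagged feature explains become the "developed unknown" class (28).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .classify import buffer_lines, classify_features, is_elevated
from .features import TaggedFeatureCollection
from .raster import CategoricalRaster, GridSpec
from .registry import DEVELOPED_UNKNOWN, UNCLASSIFIED, ClassRegistry

__all__ = [
    "ReclassMap",
    "rasterize_class",
    "merge_layers",
    "tile_and_merge",
    "reclass_global",
    "integrate",
    "build_lulc",
]

NODATA = 0


@dataclass
class ReclassMap:
    """Total map from a global raster's legend codes to framework codes.

    ``developed_codes`` lists global codes (e.g. "built/developed") that
    map to the developed-unknown class 28.
    """

    entries: dict[int, int]
    developed_codes: set[int] = field(default_factory=set)

    def lookup(self) -> dict[int, int]:
        table = dict(self.entries)
        for c in self.developed_codes:
            table[c] = DEVELOPED_UNKNOWN
        return table

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("global_code,framework_code\n")
            for g, f in sorted(self.lookup().items()):
                fh.write(f"{g},{f}\n")

    @classmethod
    def from_csv(cls, path) -> "ReclassMap":
        entries, developed = {}, set()
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                g, f = line.strip().split(",")
                g, f = int(g), int(f)
                if f == DEVELOPED_UNKNOWN:
                    developed.add(g)
                else:
                    entries[g] = f
        return cls(entries=entries, developed_codes=developed)


def rasterize_class(
    fc: TaggedFeatureCollection,
    grid: GridSpec,
    code: int,
    exclude_elevated: bool = False,
) -> CategoricalRaster:
    """Burn polygons onto the grid: cell center inside any polygon -> code.

    ``exclude_elevated`` drops bridge/tunnel-tagged features so they do
    not overwrite the layer beneath them in the later merge.
    """
    if fc.crs != grid.crs:
        raise ValueError(f"CRS mismatch: features {fc.crs!r} vs grid {grid.crs!r}")
    values = np.full(grid.shape, NODATA, dtype=np.int32)
    geoms = [
        f.geometry
        for f in fc
        if f.geometry_kind == "polygons" and not (exclude_elevated and is_elevated(f))
    ]
    if geoms:
        union = shapely.union_all(geoms)
        xs, ys = grid.cell_centers()
        shapely.prepare(union)
        inside = shapely.contains_xy(union, xs.ravel(), ys.ravel()).reshape(grid.shape)
        values[inside] = code
    return CategoricalRaster(values=values, transform=grid.transform, crs=grid.crs, nodata=NODATA)


def merge_layers(
    masks: dict[int, CategoricalRaster], reg: ClassRegistry
) -> CategoricalRaster:
    """Overlay binary class masks; per cell the highest-priority class wins."""
    if not masks:
        raise ValueError("no masks to merge")
    rasters = list(masks.values())
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError("masks are not on a common grid")
    for code in masks:
        if code not in reg.priority:
            raise ValueError(f"class {code} has no priority rank")
    out = np.full(first.shape, NODATA, dtype=np.int32)
    # ascending rank: later (higher-priority) writes win
    for code in sorted(masks, key=lambda c: reg.priority[c]):
        m = masks[code]
        out[m.values != m.nodata] = code
    return CategoricalRaster(
        values=out,
        transform=first.transform,
        crs=first.crs,
        nodata=NODATA,
        legend={c: reg.legend().get(c, str(c)) for c in masks},
    )


def tile_and_merge(
    masks: dict[int, CategoricalRaster], reg: ClassRegistry, tile_size: int
) -> CategoricalRaster:
    """Merge tile-by-tile; bit-identical to the untiled merge.

    Exists so very large study areas can be processed in bounded memory;
    the priority rule is purely cell-local, so tiling cannot change the
    result.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    # validate once (grids, priorities) via an untiled dry check of inputs
    full = next(iter(masks.values()))
    for m in masks.values():
        if not full.same_grid(m):
            raise ValueError("masks are not on a common grid")
    for code in masks:
        if code not in reg.priority:
            raise ValueError(f"class {code} has no priority rank")
    order = sorted(masks, key=lambda c: reg.priority[c])
    nrow, ncol = full.shape
    out = np.full((nrow, ncol), NODATA, dtype=np.int32)
    for r0 in range(0, nrow, tile_size):
        for c0 in range(0, ncol, tile_size):
            r1, c1 = min(r0 + tile_size, nrow), min(c0 + tile_size, ncol)
            tile = out[r0:r1, c0:c1]
            for code in order:
                m = masks[code]
                sub = m.values[r0:r1, c0:c1]
                tile[sub != m.nodata] = code
    return CategoricalRaster(
        values=out,
        transform=full.transform,
        crs=full.crs,
        nodata=NODATA,
        legend={c: reg.legend().get(c, str(c)) for c in masks},
    )


def reclass_global(global_r: CategoricalRaster, m: ReclassMap) -> CategoricalRaster:
    """Cell-wise legend lookup of the global raster into framework codes."""
    table = m.lookup()
    present = set(np.unique(global_r.values)) - {global_r.nodata}
    unmapped = sorted(present - set(table))
    if unmapped:
        raise ValueError(f"global legend codes without reclass entry: {unmapped}")
    out = np.full(global_r.shape, global_r.nodata, dtype=np.int32)
    for g, f in table.items():
        out[global_r.values == g] = f
    legend = {f: f"class_{f}" for f in table.values()}
    legend[DEVELOPED_UNKNOWN] = "developed_unknown"
    return CategoricalRaster(
        values=out,
        transform=global_r.transform,
        crs=global_r.crs,
        nodata=global_r.nodata,
        legend=legend,
    )


def integrate(
    osm_r: CategoricalRaster, global_reclassed: CategoricalRaster
) -> CategoricalRaster:
    """Backfill: keep the detailed cell where defined, else the global cell."""
    if not osm_r.same_grid(global_reclassed):
        raise ValueError("rasters are not on a common grid")
    out = np.where(osm_r.values != osm_r.nodata, osm_r.values, global_reclassed.values)
    legend = dict(global_reclassed.legend)
    legend.update(osm_r.legend)
    return CategoricalRaster(
        values=out.astype(np.int32),
        transform=osm_r.transform,
        crs=osm_r.crs,
        nodata=osm_r.nodata,
        legend=legend,
    )


def align_nearest(src: CategoricalRaster, grid: GridSpec) -> CategoricalRaster:
    """Nearest-neighbor resample of a categorical raster onto ``grid``.

    Interpolation is meaningless for class codes, so each target cell
    takes the source cell containing its center (nodata outside the
    source extent).
    """
    xs, ys = grid.cell_centers()
    sx0, sy0, ss = src.transform
    cols = np.floor((xs - sx0) / ss).astype(int)
    rows = np.floor((sy0 - ys) / ss).astype(int)
    valid = (rows >= 0) & (rows < src.shape[0]) & (cols >= 0) & (cols < src.shape[1])
    out = np.full(grid.shape, src.nodata, dtype=np.int32)
    out[valid] = src.values[rows[valid], cols[valid]]
    return CategoricalRaster(
        values=out, transform=grid.transform, crs=grid.crs, nodata=src.nodata, legend=dict(src.legend)
    )


def build_lulc(
    fc_polygons: TaggedFeatureCollection,
    fc_lines: TaggedFeatureCollection,
    reg: ClassRegistry,
    grid: GridSpec,
    exclude_elevated: bool = True,
    tile_size: int | None = None,
) -> CategoricalRaster:
    """Full overlay pipeline: classify, buffer lines, rasterize, merge.

    Returns the tagged-features-only land-cover raster (cells no feature
    explains remain nodata; integrate with a reclassified global raster to
    remove them).
    """
    by_class_poly = classify_features(fc_polygons, reg)
    by_class_line = classify_features(fc_lines, reg)
    masks: dict[int, CategoricalRaster] = {}
    for rule in reg.rules:
        code = rule.class_code
        if rule.geometry_kind == "line":
            layer = buffer_lines(by_class_line[code], reg, class_code=code)
        else:
            layer = by_class_poly[code]
        if len(layer) == 0:
            continue
        masks[code] = rasterize_class(layer, grid, code, exclude_elevated=exclude_elevated)
    if not masks:
        return CategoricalRaster(
            values=np.full(grid.shape, NODATA, dtype=np.int32),
            transform=grid.transform,
            crs=grid.crs,
            nodata=NODATA,
        )
    if tile_size:
        return tile_and_merge(masks, reg, tile_size)
    return merge_layers(masks, reg)
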