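"""The wildlife-oriented urbanization index.

The index scores each 30 m cell of the land-cover map for urban intensity,
combining, as an arithmetic weighted sum:

* focal vegetation proportions in 900 m blocks, weighted 3:2:1 for
  forest, low-height vegetation and open green (proportional to the
  shelter each provides), entering negatively;
* the focal building proportion in 450 m blocks, entering positively;
* proximity to major roads (primary, secondary, motorways) and railways —
  one minus the 0-1-normalized Euclidean distance — entering positively;
* proximity to water, entering negatively by default (water access reads
  as habitat, i.e. less urban); the sign is configuration, not dogma.

Larger values mean more urban. The raw sum is affinely rescaled so the
theoretical extremes of the default weights map to [0, 100]; the scaling
is presentation only and every weight and sign is user-overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import CategoricalRaster, FloatRaster

__all__ = [
    "IndexConfig",
    "focal_proportion",
    "distance_to",
    "normalize01",
    "urbanization_index",
]

DEFAULT_VEG_WEIGHTS = {"forest": 3.0, "low_veg": 2.0, "open_green": 1.0}


@dataclass
class IndexConfig:
    """Tunable surface of the urbanization index.

    Windows are side lengths in meters and must be positive multiples of
    the cell size (900 m and 450 m at 30 m cells, i.e. aggregation factors
    30 and 15). ``component_weights`` are signed; positive pulls toward
    "more urban". ``output_scale = (offset, factor)`` is applied last;
    ``None`` auto-scales the theoretical range to [0, 100].
    """

    veg_window: float = 900.0
    bld_window: float = 450.0
    veg_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VEG_WEIGHTS))
    component_weights: dict[str, float] = field(
        default_factory=lambda: {
            "vegetation_term": -1.0,
            "building_term": 1.0,
            "road_proximity_term": 0.5,
            "water_proximity_term": -0.25,
        }
    )
    forest_codes: frozenset = frozenset({8})
    low_veg_codes: frozenset = frozenset({9})
    open_green_codes: frozenset = frozenset({10})
    building_codes: frozenset = frozenset({14})
    major_road_codes: frozenset = frozenset({16, 18, 19, 24})
    water_codes: frozenset = frozenset({12})
    output_scale: tuple[float, float] | None = None

    def theoretical_range(self) -> tuple[float, float]:
        """Bounds of the raw sum: each component term lies in [0, 1]."""
        w = self.component_weights
        lo = sum(min(0.0, v) for v in w.values())
        hi = sum(max(0.0, v) for v in w.values())
        return lo, hi

    def resolve_scale(self) -> tuple[float, float]:
        if self.output_scale is not None:
            return self.output_scale
        lo, hi = self.theoretical_range()
        factor = 100.0 / (hi - lo)
        return (-lo * factor, factor)


def focal_proportion(mask: CategoricalRaster, window: float) -> FloatRaster:
    """Block proportion of coded cells, disaggregated back to the grid.

    The grid is aggregated at factor ``window / cell_size`` (each block's
    value is the fraction of its cells that carry the mask's code), then
    each block value is repeated over its cells. Edge blocks shorter than
    the factor use their actual cell count.
    """
    s = mask.cell_size
    factor = window / s
    if window < s or abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"window {window} is not a positive multiple of cell size {s}")
    factor = int(round(factor))
    coded = (mask.values != mask.nodata).astype(float)
    nrow, ncol = coded.shape
    r_edges = np.arange(0, nrow, factor)
    c_edges = np.arange(0, ncol, factor)
    sums = np.add.reduceat(np.add.reduceat(coded, r_edges, axis=0), c_edges, axis=1)
    counts = np.outer(
        np.diff(np.append(r_edges, nrow)), np.diff(np.append(c_edges, ncol))
    ).astype(float)
    frac = sums / counts
    out = np.repeat(np.repeat(frac, factor, axis=0), factor, axis=1)[:nrow, :ncol]
    return FloatRaster(values=out, transform=mask.transform, crs=mask.crs)


def distance_to(r: CategoricalRaster, targets) -> FloatRaster:
    """Euclidean distance (m) from each cell center to the nearest target
    cell center; target cells are 0."""
    target_mask = r.mask(targets)
    if not target_mask.any():
        raise ValueError(f"no cells with codes {sorted(targets)} in raster")
    dist = ndimage.distance_transform_edt(~target_mask) * r.cell_size
    return FloatRaster(values=dist, transform=r.transform, crs=r.crs)


def normalize01(r: FloatRaster) -> FloatRaster:
    """Min-max rescale to [0, 1]; errors on a constant raster."""
    v = r.values
    lo, hi = float(np.nanmin(v)), float(np.nanmax(v))
    if hi == lo:
        raise ValueError("constant raster: 0-1 normalization undefined")
    return FloatRaster(values=(v - lo) / (hi - lo), transform=r.transform, crs=r.crs)


def _binary(r: CategoricalRaster, codes) -> CategoricalRaster:
    vals = np.where(r.mask(codes), 1, 0).astype(np.int32)
    return CategoricalRaster(values=vals, transform=r.transform, crs=r.crs, nodata=0)


def urbanization_index(lulc: CategoricalRaster, cfg: IndexConfig | None = None) -> FloatRaster:
    """Compute the index on the land-cover raster's own grid.

    raw = w_v * (3*P_forest + 2*P_lowveg + 1*P_open)/6
        + w_b * P_building
        + w_r * (1 - Dhat_road)
        + w_w * (1 - Dhat_water)

    with P the focal proportions, Dhat the 0-1-normalized distances, and
    w the signed component weights (vegetation negative by default, so the
    index is strictly increasing in building proportion and decreasing in
    each vegetation proportion). ``output_scale`` is applied last.
    """
    cfg = cfg or IndexConfig()
    vw = cfg.veg_weights
    wsum = vw["forest"] + vw["low_veg"] + vw["open_green"]
    p_forest = focal_proportion(_binary(lulc, cfg.forest_codes), cfg.veg_window).values
    p_lowveg = focal_proportion(_binary(lulc, cfg.low_veg_codes), cfg.veg_window).values
    p_open = focal_proportion(_binary(lulc, cfg.open_green_codes), cfg.veg_window).values
    vegetation = (vw["forest"] * p_forest + vw["low_veg"] * p_lowveg + vw["open_green"] * p_open) / wsum

    p_bld = focal_proportion(_binary(lulc, cfg.building_codes), cfg.bld_window).values

    d_road = normalize01(distance_to(lulc, cfg.major_road_codes)).values
    d_water = normalize01(distance_to(lulc, cfg.water_codes)).values

    w = cfg.component_weights
    raw = (
        w["vegetation_term"] * vegetation
        + w["building_term"] * p_bld
        + w["road_proximity_term"] * (1.0 - d_road)
        + w["water_proximity_term"] * (1.0 - d_water)
    )
    offset, factor = cfg.resolve_scale()
    return FloatRaster(values=offset + factor * raw, transform=lulc.transform, crs=lulc.crs)
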