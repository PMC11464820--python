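"""Gridded raster containers and GeoTIFF I/O.

Rasters follow the north-up convention: ``transform = (x0, y0, cell)`` maps
the upper-left corner of cell ``(0, 0)`` to world coordinate ``(x0, y0)``;
cell ``(row, col)`` covers the half-open square
``[x0 + col*s, x0 + (col+1)*s) x (y0 - (row+1)*s, y0 - row*s]`` and its
center is at ``(x0 + (col+0.5)*s, y0 - (row+0.5)*s)``.

GeoTIFF files are written with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA); the CRS identifier and the
class legend travel in the image description as JSON so that a
write-then-read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "GridSpec",
    "CategoricalRaster",
    "FloatRaster",
    "read_raster",
    "write_raster",
]

# GeoTIFF tag numbers
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GridSpec:
    """A working grid: a bounding box snapped outward to the cell size.

    Parameters
    ----------
    bbox : (xmin, ymin, xmax, ymax) in meters.
    cell_size : cell side length in meters (default 30, the working
        resolution of the land-cover framework).
    crs : identifier of the projected CRS the coordinates live in.
    """

    bbox: tuple[float, float, float, float]
    cell_size: float = 30.0
    crs: str = "local-meters"

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        s = self.cell_size
        # snap outward so sides are whole multiples of the cell size
        snapped = (
            np.floor(xmin / s) * s,
            np.floor(ymin / s) * s,
            np.ceil(xmax / s) * s,
            np.ceil(ymax / s) * s,
        )
        object.__setattr__(self, "bbox", tuple(float(v) for v in snapped))

    @property
    def shape(self) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.bbox
        s = self.cell_size
        return (int(round((ymax - ymin) / s)), int(round((xmax - xmin) / s)))

    @property
    def transform(self) -> tuple[float, float, float]:
        xmin, _, _, ymax = self.bbox
        return (xmin, ymax, self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (xs, ys) 2-D arrays of cell-center coordinates."""
        nrow, ncol = self.shape
        x0, y0, s = self.transform
        xs = x0 + (np.arange(ncol) + 0.5) * s
        ys = y0 - (np.arange(nrow) + 0.5) * s
        return np.meshgrid(xs, ys)


class _Gridded:
    """Shared grid/georeferencing behaviour for raster containers."""

    values: np.ndarray
    transform: tuple[float, float, float]
    crs: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform[2]

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def grid(self) -> GridSpec:
        x0, y0, s = self.transform
        nrow, ncol = self.values.shape
        return GridSpec((x0, y0 - nrow * s, x0 + ncol * s, y0), s, self.crs)

    def same_grid(self, other: "_Gridded") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.transform, other.transform)
            and self.crs == other.crs
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid().cell_centers()


@dataclass
class CategoricalRaster(_Gridded):
    """Integer class-code grid with affine georeferencing and a legend.

    ``nodata`` is a code outside the legend (0 by default; framework codes
    run 1-28). Every non-nodata cell's code must appear in the legend when
    a legend is supplied.
    """

    values: np.ndarray
    transform: tuple[float, float, float]
    crs: str = "local-meters"
    nodata: int = 0
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")
        if not np.issubdtype(self.values.dtype, np.integer):
            self.values = self.values.astype(np.int32)
        if self.legend and self.nodata in self.legend:
            raise ValueError(
                f"nodata code {self.nodata} collides with legend entry "
                f"{self.legend[self.nodata]!r}"
            )
        if self.legend:
            present = np.unique(self.values)
            bad = [c for c in present if c != self.nodata and c not in self.legend]
            if bad:
                raise ValueError(f"codes {bad} not in legend")

    def mask(self, codes) -> np.ndarray:
        """Boolean grid: cell code in ``codes``."""
        return np.isin(self.values, list(codes))

    def area_of(self, code: int) -> float:
        """Total area (m^2) of cells holding ``code``."""
        return float(np.count_nonzero(self.values == code)) * self.cell_area


@dataclass
class FloatRaster(_Gridded):
    """Continuous-valued grid sharing the categorical raster's geometry."""

    values: np.ndarray
    transform: tuple[float, float, float]
    crs: str = "local-meters"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D grid")


def write_raster(r, path) -> None:
    """Write a raster to GeoTIFF with georeferencing and legend metadata."""
    x0, y0, s = r.transform
    meta = {"crs": r.crs}
    if isinstance(r, CategoricalRaster):
        meta["nodata"] = int(r.nodata)
        meta["legend"] = {str(k): v for k, v in r.legend.items()}
        data = r.values.astype(np.int32)
    else:
        data = r.values.astype(np.float64)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (float(s), float(s), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]
    if isinstance(r, CategoricalRaster):
        extratags.append((_GDAL_NODATA, "s", 0, str(int(r.nodata))))
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=extratags,
        photometric="minisblack",
    )


def read_raster(path):
    """Read a GeoTIFF written by :func:`write_raster`.

    Integer grids come back as :class:`CategoricalRaster`, float grids as
    :class:`FloatRaster`; transform, nodata, CRS and legend round-trip
    bit-identically.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        s = float(scale[0])
        x0, y0 = float(tie[3]), float(tie[4])
        desc = page.description
    meta = json.loads(desc) if desc else {}
    crs = meta.get("crs", "local-meters")
    transform = (x0, y0, s)
    if np.issubdtype(values.dtype, np.integer):
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
        return CategoricalRaster(
            values=values,
            transform=transform,
            crs=crs,
            nodata=int(meta.get("nodata", 0)),
            legend=legend,
        )
    return FloatRaster(values=values, transform=transform, crs=crs)
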