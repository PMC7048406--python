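"""Minimal single-band georeferenced rasters with GeoTIFF I/O.

A raster is a 2-d float grid plus a north-up affine geotransform (no
rotation), a nodata sentinel and a CRS tag. Cell (0, 0) sits at the
top-left; cells are half-open intervals, so a point maps to the cell given
by the floor of the inverse geotransform.

GeoTIFFs are written and read through :mod:`tifffile` using the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and GDAL's
nodata tag, which is sufficient for single-band, north-up imagery; writes
are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_NODATA = -9999.0

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine map between cell indices and world coordinates.

    ``x0, y0`` is the world coordinate of the top-left corner of cell (0, 0);
    ``dx > 0`` and ``dy < 0`` are the cell sizes along x (columns) and y
    (rows), dy negative because row indices grow downward.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self):
        if self.dx <= 0 or self.dy >= 0:
            raise ValueError(f"require dx > 0 and dy < 0, got dx={self.dx}, dy={self.dy}")

    def pixel_center(self, row: int, col: int) -> Tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.dx, self.y0 + (row + 0.5) * self.dy)

    def world_to_pixel(self, x: float, y: float) -> Tuple[int, int]:
        """Containing cell of a point: half-open cells, floor convention."""
        col = int(np.floor((x - self.x0) / self.dx))
        row = int(np.floor((y - self.y0) / self.dy))
        return row, col


@dataclass(frozen=True)
class Raster:
    """A single-band float raster."""

    data: np.ndarray
    transform: GeoTransform
    nodata: float = DEFAULT_NODATA
    crs: Optional[str] = "EPSG:32650"

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("raster data must be 2-d")
        object.__setattr__(self, "data", arr)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.data.shape[0] and 0 <= col < self.data.shape[1]


@dataclass(frozen=True)
class NdviRaster(Raster):
    """NDVI grid; valid cells are expected in [-1, 1] (enforced at inversion)."""


@dataclass(frozen=True)
class BiomassRaster(Raster):
    """Predicted biomass grid (g m^-2) with a saturation mask.

    ``saturation_mask`` is True where the predicted biomass exceeds the
    NDVI-saturation threshold and the estimate is considered unreliable.
    """

    saturation_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        mask = self.saturation_mask
        if mask is None:
            mask = np.zeros(self.data.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.data.shape:
            raise ValueError("saturation mask shape must match data")
        object.__setattr__(self, "saturation_mask", mask)


def _epsg_code(crs: Optional[str]) -> Optional[int]:
    if crs and crs.upper().startswith("EPSG:"):
        try:
            return int(crs.split(":", 1)[1])
        except ValueError:
            return None
    return None


def write_geotiff(path, raster: Raster) -> None:
    """Write a single-band float64 GeoTIFF with geotransform and nodata tags."""
    t = raster.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, -t.dy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{raster.nodata:g}"),
    ]
    epsg = _epsg_code(raster.crs)
    if epsg is not None:
        # GeoKey directory: projected model type + the EPSG code.
        keys = (1, 1, 0, 3, 1024, 0, 1, 1, 3072, 0, 1, epsg, 1025, 0, 1, 1)
        extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys))
    tifffile.imwrite(
        Path(path),
        raster.data.astype(np.float64),
        extratags=extratags,
        software="grassinvert",
    )


def read_geotiff(path, cls=Raster) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or similar)."""
    with tifffile.TiffFile(Path(path)) as tf:
        page = tf.pages[0]
        data = page.asarray()
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
            tie = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing GeoTIFF geotransform tags") from exc
        x0, y0 = float(tie[3]), float(tie[4])
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs = None
        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = tags[_TAG_GEO_KEY_DIRECTORY].value
            for i in range(4, len(keys) - 3, 4):
                if keys[i] == 3072:
                    crs = f"EPSG:{keys[i + 3]}"
    return cls(
        data=np.asarray(data, dtype=float),
        transform=GeoTransform(x0=x0, y0=y0, dx=float(sx), dy=-float(sy)),
        nodata=nodata,
        crs=crs,
    )
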