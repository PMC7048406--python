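"""Raster inversion: NDVI grid -> biomass grid, and point extraction.

Applies the composite inversion model cell by cell to a satellite NDVI
raster. Nodata propagates; in-range checking is strict (valid NDVI must lie
in [-1, 1]; out-of-range cells become nodata, with a logged count). Cells
whose predicted biomass exceeds the saturation threshold — the canopy
density beyond which NDVI loses sensitivity and the estimate becomes
unreliable — are flagged in a boolean mask, not clamped or censored.

Point extraction returns the value of the pixel containing each point
(nearest-cell, no interpolation), mirroring the practice of reading the
predicted biomass of the pixel a field test point falls in.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .crosscal import CompositeModel
from .raster import BiomassRaster, NdviRaster

logger = logging.getLogger(__name__)

#: Biomass (g m^-2) above which NDVI saturation makes estimates unreliable.
DEFAULT_SATURATION_THRESHOLD = 250.0


def apply_model(
    raster: NdviRaster,
    model: CompositeModel,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
) -> BiomassRaster:
    """Cellwise biomass inversion of an NDVI raster.

    Returns a :class:`BiomassRaster` with the same geotransform and nodata
    sentinel. Input nodata cells stay nodata; valid cells with NDVI outside
    [-1, 1] are set to nodata (their count is logged); the saturation mask is
    True where predicted biomass exceeds ``saturation_threshold``.
    """
    ndvi = raster.data
    valid = raster.valid_mask()
    in_range = valid & (ndvi >= -1.0) & (ndvi <= 1.0)
    n_out = int(np.count_nonzero(valid & ~in_range))
    if n_out:
        logger.warning("%d cell(s) with NDVI outside [-1, 1] set to nodata", n_out)
    if not valid.any():
        logger.warning("all-nodata NDVI raster; biomass raster is all nodata")

    out = np.full(ndvi.shape, raster.nodata, dtype=float)
    if in_range.any():
        out[in_range] = model.evaluate(ndvi[in_range])
    mask = np.zeros(ndvi.shape, dtype=bool)
    mask[in_range] = out[in_range] > saturation_threshold
    return BiomassRaster(
        data=out,
        transform=raster.transform,
        nodata=raster.nodata,
        crs=raster.crs,
        saturation_mask=mask,
    )


def extract_at_points(
    raster: BiomassRaster,
    points: pd.DataFrame,
    x_col: str = "x",
    y_col: str = "y",
    id_col: str = "point_id",
) -> pd.DataFrame:
    """Read the predicted biomass of the pixel containing each point.

    Parameters
    ----------
    points : DataFrame with columns ``point_id``, ``x``, ``y`` (world
        coordinates in the raster's CRS).

    Returns
    -------
    DataFrame with columns point_id, predicted_agb_g_m2, saturated, status.
    ``status`` is ``"ok"``, ``"nodata"`` (pixel carries the sentinel;
    predicted value is NaN) or ``"out_of_bounds"`` (point outside the grid;
    value NaN) — per-point entries, never an exception.
    """
    rows = []
    for rec in points.itertuples(index=False):
        pid = getattr(rec, id_col)
        x, y = float(getattr(rec, x_col)), float(getattr(rec, y_col))
        row, col = raster.transform.world_to_pixel(x, y)
        if not raster.contains(row, col):
            rows.append((pid, np.nan, False, "out_of_bounds"))
            continue
        value = raster.data[row, col]
        if value == raster.nodata:
            rows.append((pid, np.nan, False, "nodata"))
        else:
            rows.append((pid, float(value), bool(raster.saturation_mask[row, col]), "ok"))
    out = pd.DataFrame(rows, columns=[id_col, "predicted_agb_g_m2", "saturated", "status"])
    n_bad = int((out["status"] != "ok").sum())
    if n_bad:
        logger.warning("%d point(s) without a valid prediction", n_bad)
    return out
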