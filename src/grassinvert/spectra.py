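"""Ground spectra to NDVI.

Converts raw spectrometer counts to reflectance, resamples reflectance into
the broadband RED (630-680 nm) and NIR (845-885 nm) windows, and computes the
normalized difference vegetation index

    NDVI = (NIR - RED) / (NIR + RED)

at the quadrat (1 x 1 m sampling unit) and plot (30 x 30 m, one satellite
pixel) levels.

Conventions, stated because a field protocol leaves them open:

* band resampling is the unweighted mean of reflectance over channels whose
  centers fall inside the window, endpoints inclusive on both sides;
* a quadrat observed by several spectra gets the mean of per-spectrum NDVIs
  (mean-of-NDVI), not the NDVI of the mean spectrum;
* calibrated reflectance is clipped to [0, 1.2] — field reference panels
  commonly yield values slightly above 1 — with a logged warning rather than
  a hard failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BandCoverageError, CalibrationError, UndefinedNdviError

logger = logging.getLogger(__name__)

#: Maximum physically admitted reflectance after calibration.
REFLECTANCE_CAP = 1.2


@dataclass(frozen=True)
class BandDefinition:
    """A broadband window on the wavelength axis, in nm, endpoints inclusive."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low ({self.low}) must be < high ({self.high})")

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        return (wavelengths >= self.low) & (wavelengths <= self.high)


RED = BandDefinition("RED", 630.0, 680.0)
NIR = BandDefinition("NIR", 845.0, 885.0)


@dataclass(frozen=True)
class Spectrum:
    """One quadrat's reflectance spectrum.

    Parameters
    ----------
    wavelengths : array of nm, strictly increasing.
    reflectance : unitless reflectance per channel, finite, in [0, 1.2].
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", rf)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise ValueError("wavelengths and reflectance must be 1-d arrays of equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(rf)):
            raise ValueError("reflectance must be finite")
        if rf.min() < 0 or rf.max() > REFLECTANCE_CAP:
            raise ValueError(f"reflectance must lie in [0, {REFLECTANCE_CAP}]")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class BroadbandReflectance:
    """Mean reflectance over the RED and NIR windows of one spectrum."""

    red: float
    nir: float

    def __post_init__(self):
        if not (np.isfinite(self.red) and np.isfinite(self.nir)):
            raise ValueError("broadband reflectance must be finite")
        if self.red < 0 or self.nir < 0:
            raise ValueError("broadband reflectance must be >= 0")


def calibrate_reflectance(
    wavelengths: Sequence[float],
    target_counts: Sequence[float],
    panel_counts: Sequence[float],
    dark_counts: Sequence[float],
    panel_reflectivity: float = 1.0,
) -> Spectrum:
    """Raw counts to reflectance against a reference panel.

    reflectance(lambda) = (target - dark) / (panel - dark) * panel_reflectivity

    The dark-current vector is subtracted from both the target and the panel
    signal; the result is clipped to [0, 1.2] (values above 1 occur with real
    panels and are kept, with a warning, up to the cap).

    Raises
    ------
    CalibrationError
        If the panel signal does not exceed dark current at some channel; the
        message names the first offending channel.
    """
    wl = np.asarray(wavelengths, dtype=float)
    tgt = np.asarray(target_counts, dtype=float)
    pan = np.asarray(panel_counts, dtype=float)
    drk = np.asarray(dark_counts, dtype=float)
    if not (wl.shape == tgt.shape == pan.shape == drk.shape):
        raise ValueError("wavelengths, target, panel and dark must have equal lengths")
    bad = np.nonzero(pan <= drk)[0]
    if bad.size:
        ch = int(bad[0])
        raise CalibrationError(
            f"panel counts <= dark counts at channel {ch} ({wl[ch]:g} nm); "
            f"{bad.size} channel(s) affected"
        )
    refl = (tgt - drk) / (pan - drk) * panel_reflectivity
    n_over = int(np.count_nonzero(refl > REFLECTANCE_CAP))
    n_under = int(np.count_nonzero(refl < 0))
    if n_over or n_under:
        logger.warning(
            "calibrated reflectance clipped to [0, %.1f] at %d channel(s)",
            REFLECTANCE_CAP,
            n_over + n_under,
        )
    return Spectrum(wl, np.clip(refl, 0.0, REFLECTANCE_CAP))


def resample_band(spectrum: Spectrum, band: BandDefinition) -> float:
    """Unweighted mean reflectance over channels with centers inside the band."""
    mask = band.contains(spectrum.wavelengths)
    if not mask.any():
        raise BandCoverageError(
            f"no channel inside {band.name} window [{band.low}, {band.high}] nm "
            f"(spectrum spans {spectrum.wavelengths[0]:g}-{spectrum.wavelengths[-1]:g} nm)"
        )
    return float(spectrum.reflectance[mask].mean())


def broadband(spectrum: Spectrum, red: BandDefinition = RED, nir: BandDefinition = NIR) -> BroadbandReflectance:
    """Resample a spectrum into the two NDVI windows."""
    return BroadbandReflectance(red=resample_band(spectrum, red), nir=resample_band(spectrum, nir))


def compute_ndvi(bb: BroadbandReflectance) -> float:
    """NDVI = (nir - red) / (nir + red); raises rather than returning a silent 0."""
    denom = bb.nir + bb.red
    if denom == 0:
        raise UndefinedNdviError("nir + red = 0: NDVI undefined")
    return float((bb.nir - bb.red) / denom)


def spectrum_ndvi(spectrum: Spectrum, red: BandDefinition = RED, nir: BandDefinition = NIR) -> float:
    """NDVI of a single spectrum via its broadband means."""
    return compute_ndvi(broadband(spectrum, red, nir))


def quadrat_ndvi(
    spectra: Iterable[Spectrum], red: BandDefinition = RED, nir: BandDefinition = NIR
) -> float:
    """Quadrat NDVI: mean of per-spectrum NDVIs (mean-of-NDVI convention)."""
    values = [spectrum_ndvi(s, red, nir) for s in spectra]
    if not values:
        raise ValueError("quadrat_ndvi needs at least one spectrum")
    return float(np.mean(values))


def plot_mean_ndvi(quadrat_ndvis: Sequence[float]) -> float:
    """Plot-level NDVI: arithmetic mean of its quadrat NDVIs."""
    vals = np.asarray(quadrat_ndvis, dtype=float)
    if vals.size == 0:
        raise ValueError("plot_mean_ndvi needs at least one quadrat NDVI")
    return float(vals.mean())


def ndvi_table(
    spectra_long: pd.DataFrame,
    red: BandDefinition = RED,
    nir: BandDefinition = NIR,
) -> pd.DataFrame:
    """Per-quadrat NDVI from a long-format spectra table.

    Parameters
    ----------
    spectra_long : DataFrame with columns quadrat_id, wavelength_nm,
        reflectance (one row per channel), optionally spectrum_id when a
        quadrat has several spectra.

    Returns
    -------
    DataFrame with columns quadrat_id, soc_ndvi, sorted by quadrat_id.
    """
    required = {"quadrat_id", "wavelength_nm", "reflectance"}
    missing = required - set(spectra_long.columns)
    if missing:
        raise ValueError(f"spectra table missing columns: {sorted(missing)}")
    group_cols = ["quadrat_id"]
    spectrum_col = "spectrum_id" if "spectrum_id" in spectra_long.columns else None
    rows = []
    for qid, qdf in spectra_long.groupby(group_cols[0], sort=True):
        if spectrum_col:
            spectra = [
                Spectrum(sdf["wavelength_nm"].to_numpy(), sdf["reflectance"].to_numpy())
                for _, sdf in qdf.groupby(spectrum_col, sort=True)
            ]
        else:
            qdf = qdf.sort_values("wavelength_nm")
            spectra = [Spectrum(qdf["wavelength_nm"].to_numpy(), qdf["reflectance"].to_numpy())]
        rows.append({"quadrat_id": qid, "soc_ndvi": quadrat_ndvi(spectra, red, nir)})
    return pd.DataFrame(rows)
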