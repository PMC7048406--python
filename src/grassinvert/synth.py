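"""Synthetic field campaign generator.

Emulates a grassland biomass survey in which hyperspectral reflectance and
clipped dry biomass are measured in 1 x 1 m quadrats nested inside
30 x 30 m plots, each plot matching one satellite pixel:

* quadrat spectra are linear vegetation/soil endmember mixtures on a
  spectrometer-like wavelength grid (400-1000 nm, 2.3 nm steps), with
  optional additive reflectance noise;
* quadrat biomass follows an exponential law in the quadrat's *realized*
  ground NDVI, AGB = a * e**(b * NDVI) * (1 + eps), with multiplicative
  relative noise eps ~ Normal(0, cv) and a small positive floor (an
  exponential mean with additive constant noise would go negative at low
  NDVI);
* plot-level satellite NDVI is tied to the plot-mean ground NDVI through the
  inverse of the linear cross-calibration SOC = c*TM + d, plus additive
  noise, clipped to the valid NDVI range;
* a small NDVI raster holds each plot's satellite NDVI at its pixel and the
  nodata sentinel elsewhere.

Campaign defaults mirror the study design the analysis assumes: 39 plots,
173 quadrats, ground law a = 12.523 g m^-2, b = 3.370, cross-calibration
c = 0.462, d = 0.413, biomass CV 0.2. Identical config + seed reproduces
every table and the raster byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import spectra as sp
from .errors import BandCoverageError, DegenerateModelError, DomainError
from .raster import DEFAULT_NODATA, GeoTransform, NdviRaster, write_geotiff

_CSV_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class CampaignConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_plots: int = 39
    n_quadrats: int = 173
    #: Ground law AGB = a * e**(b * SOC_NDVI); a in g m^-2.
    ground_a: float = 12.523
    ground_b: float = 3.370
    #: Cross-calibration SOC_NDVI = c * TM_NDVI + d.
    cross_c: float = 0.462
    cross_d: float = 0.413
    #: Relative (CV) noise on biomass.
    agb_noise_cv: float = 0.2
    #: Additive noise on plot satellite NDVI.
    ndvi_noise_sd: float = 0.02
    #: Additive reflectance noise on quadrat spectra.
    spectrum_noise_sd: float = 0.005
    #: Plot-level vegetation-cover means are uniform on this interval.
    cover_range: Tuple[float, float] = (0.20, 0.85)
    #: Quadrat cover scatters around its plot mean with this sd.
    within_plot_cover_sd: float = 0.08
    #: Spectrometer wavelength grid, nm.
    wavelength_start: float = 400.0
    wavelength_stop: float = 1000.0
    wavelength_step: float = 2.3
    #: Raster geometry: grid size, 30 m pixels.
    raster_shape: Tuple[int, int] = (50, 50)
    pixel_size: float = 30.0
    origin: Tuple[float, float] = (400000.0, 4900000.0)
    nodata: float = DEFAULT_NODATA
    crs: str = "EPSG:32650"
    agb_floor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 2:
            raise ValueError("need at least 2 plots")
        if self.n_quadrats < self.n_plots:
            raise ValueError("need at least one quadrat per plot")
        if self.ground_a <= 0:
            raise ValueError("ground_a must be > 0")
        if self.cross_c == 0:
            raise DegenerateModelError("cross-model slope c = 0 cannot be inverted")
        lo, hi = self.cover_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("cover_range must be an interval within [0, 1]")
        for name in ("agb_noise_cv", "ndvi_noise_sd", "spectrum_noise_sd", "within_plot_cover_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.raster_shape[0] * self.raster_shape[1] < self.n_plots:
            raise ValueError("raster too small to hold one pixel per plot")

    def wavelength_grid(self) -> np.ndarray:
        return np.arange(self.wavelength_start, self.wavelength_stop, self.wavelength_step)

    def quadrats_per_plot(self) -> np.ndarray:
        """Deterministic near-even allocation: the first plots take the extras."""
        base, extra = divmod(self.n_quadrats, self.n_plots)
        counts = np.full(self.n_plots, base, dtype=int)
        counts[:extra] += 1
        return counts

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticCampaign:
    """One realized campaign: tables, raster and provenance."""

    quadrats: pd.DataFrame  # quadrat_id, plot_id, soc_ndvi, agb_g_m2
    plots: pd.DataFrame  # plot_id, soc_ndvi_mean, tm_ndvi, row, col, x, y
    spectra: pd.DataFrame  # quadrat_id, wavelength_nm, reflectance
    raster: NdviRaster
    config: CampaignConfig


def make_endmembers(wavelengths: np.ndarray) -> Tuple[sp.Spectrum, sp.Spectrum]:
    """Idealized vegetation and bare-soil reflectance endmembers.

    Vegetation: strong chlorophyll absorption in the red, a logistic red edge
    near 718 nm, an NIR plateau, and a small green bump — giving a red-window
    mean well below the NIR-window mean (NDVI ~ 0.89). Soil: a gently rising
    line with near-zero NDVI. Only the band-window means matter downstream.
    """
    wl = np.asarray(wavelengths, dtype=float)
    for band in (sp.RED, sp.NIR):
        if not band.contains(wl).any():
            raise BandCoverageError(
                f"wavelength grid {wl[0]:g}-{wl[-1]:g} nm misses the "
                f"{band.name} window [{band.low}, {band.high}] nm"
            )
    red_edge = 1.0 / (1.0 + np.exp(-(wl - 718.0) / 10.0))
    green_bump = 0.04 * np.exp(-(((wl - 550.0) / 30.0) ** 2))
    veg = 0.03 + 0.52 * red_edge + green_bump
    soil = 0.10 + 0.00015 * (wl - 400.0)
    return sp.Spectrum(wl, np.clip(veg, 0.0, 1.0)), sp.Spectrum(wl, np.clip(soil, 0.0, 1.0))


def simulate_quadrat_spectrum(
    cover: float,
    endmembers: Tuple[sp.Spectrum, sp.Spectrum],
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> sp.Spectrum:
    """Linear vegetation/soil mixture at fractional cover, plus noise.

    reflectance = cover * veg + (1 - cover) * soil + Normal(0, noise_sd),
    clipped to [0, 1.2].
    """
    if not 0.0 <= cover <= 1.0:
        raise DomainError(f"cover must be in [0, 1], got {cover}")
    veg, soil = endmembers
    if not np.array_equal(veg.wavelengths, soil.wavelengths):
        raise ValueError("endmembers must share a wavelength grid")
    refl = cover * veg.reflectance + (1.0 - cover) * soil.reflectance
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        refl = refl + rng.normal(0.0, noise_sd, refl.size)
    return sp.Spectrum(veg.wavelengths, np.clip(refl, 0.0, sp.REFLECTANCE_CAP))


def simulate_campaign(config: CampaignConfig) -> SyntheticCampaign:
    """Generate a full campaign; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    wl = config.wavelength_grid()
    endmembers = make_endmembers(wl)

    counts = config.quadrats_per_plot()
    plot_ids = [f"P{i + 1:03d}" for i in range(config.n_plots)]
    plot_cover = rng.uniform(*config.cover_range, config.n_plots)

    # distinct raster pixels, one per plot
    n_cells = config.raster_shape[0] * config.raster_shape[1]
    flat = rng.choice(n_cells, size=config.n_plots, replace=False)
    rows_px, cols_px = np.divmod(flat, config.raster_shape[1])

    quadrat_rows = []
    spectra_frames = []
    plot_soc_means = []
    q_index = 0
    for p, pid in enumerate(plot_ids):
        soc_vals = []
        for _ in range(counts[p]):
            q_index += 1
            qid = f"Q{q_index:04d}"
            cover = float(np.clip(rng.normal(plot_cover[p], config.within_plot_cover_sd), 0.0, 1.0))
            spec = simulate_quadrat_spectrum(
                cover, endmembers, noise_sd=config.spectrum_noise_sd, rng=rng
            )
            soc = sp.spectrum_ndvi(spec)
            eps = rng.normal(0.0, config.agb_noise_cv) if config.agb_noise_cv > 0 else 0.0
            agb = config.ground_a * np.exp(config.ground_b * soc) * (1.0 + eps)
            agb = max(agb, config.agb_floor)
            soc_vals.append(soc)
            quadrat_rows.append(
                {"quadrat_id": qid, "plot_id": pid, "soc_ndvi": soc, "agb_g_m2": agb}
            )
            spectra_frames.append(
                pd.DataFrame(
                    {"quadrat_id": qid, "wavelength_nm": wl, "reflectance": spec.reflectance}
                )
            )
        plot_soc_means.append(float(np.mean(soc_vals)))

    plot_soc_means = np.asarray(plot_soc_means)
    eta = (
        rng.normal(0.0, config.ndvi_noise_sd, config.n_plots)
        if config.ndvi_noise_sd > 0
        else np.zeros(config.n_plots)
    )
    tm = np.clip((plot_soc_means - config.cross_d) / config.cross_c + eta, -1.0, 1.0)

    transform = GeoTransform(
        x0=config.origin[0], y0=config.origin[1], dx=config.pixel_size, dy=-config.pixel_size
    )
    grid = np.full(config.raster_shape, config.nodata, dtype=float)
    grid[rows_px, cols_px] = tm
    raster = NdviRaster(data=grid, transform=transform, nodata=config.nodata, crs=config.crs)

    centers = [transform.pixel_center(r, c) for r, c in zip(rows_px, cols_px)]
    plots = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "soc_ndvi_mean": plot_soc_means,
            "tm_ndvi": tm,
            "row": rows_px,
            "col": cols_px,
            "x": [c[0] for c in centers],
            "y": [c[1] for c in centers],
        }
    )
    return SyntheticCampaign(
        quadrats=pd.DataFrame(quadrat_rows),
        plots=plots,
        spectra=pd.concat(spectra_frames, ignore_index=True),
        raster=raster,
        config=config,
    )


def write_campaign(campaign: SyntheticCampaign, outdir) -> None:
    """Write quadrats.csv, plots.csv, spectra.csv, ndvi.tif, provenance.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    campaign.quadrats.to_csv(out / "quadrats.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    campaign.plots.to_csv(out / "plots.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    campaign.spectra.to_csv(out / "spectra.csv", index=False, float_format=_CSV_FLOAT_FORMAT)
    write_geotiff(out / "ndvi.tif", campaign.raster)
    (out / "provenance.json").write_text(
        json.dumps({"config": campaign.config.to_dict()}, indent=2, sort_keys=True) + "\n"
    )
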