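# Methods

## The inversion chain

The package estimates grassland aboveground biomass (AGB, g m⁻² dry weight)
from satellite NDVI by composing two empirical regressions measured in a
ground campaign: an exponential ground model `AGB = a·e^(b·SOC_NDVI)` fitted
on quadrat data, and a plot-level linear cross-calibration
`SOC_NDVI = c·TM_NDVI + d` between ground and satellite NDVI. The composite
`AGB(t) = a·e^(b·(c·t + d))` is applied to NDVI rasters. The chain assumes
(i) a single vegetation stratum — one ground law for the whole scene;
(ii) plot-mean quadrat NDVI is representative of the 30 × 30 m pixel it
sits in; (iii) the sensors' NDVI difference is affine at plot scale; and
(iv) contemporaneous acquisition of field and satellite data.

## NDVI and spectral conventions

* Band windows: RED 630–680 nm, NIR 845–885 nm, endpoints inclusive.
* Band resampling is the unweighted mean of reflectance over channels whose
  centers fall in the window — not trapezoidal integration or
  spectral-response weighting. The windows span ~22 and ~17 channels of a
  2.3 nm instrument grid, so the methods agree to well under 1 % (a test
  compares a 2.3 nm against a 1 nm grid, tolerance 0.005 absolute).
* A quadrat observed by several spectra gets the **mean of per-spectrum
  NDVIs**, not the NDVI of the mean spectrum; the two differ for
  heterogeneous quadrats and the choice is declared, not derivable.
* Calibration: `(target − dark)/(panel − dark) × panel reflectivity`,
  clipped to [0, 1.2] with a warning — field reference panels commonly yield
  slightly super-unit reflectance, and a hard failure would discard usable
  spectra. A panel signal at or below dark current is an error naming the
  channel.
* NDVI with a zero denominator raises rather than returning a silent 0.

## Regression families and statistics

Power and exponential coefficients come from log-linearized OLS (`ln y` on
`ln x` or `x`), the spreadsheet-trendline convention behind printed
equations of this form; it is deterministic and reproducible. A nonlinear
least-squares refinement (`refine=True`, started from the log-linear
solution) exists but is off by default. R² is reported on the original
response scale, `1 − SS_res/SS_tot` with back-transformed predictions;
because published values of such fits are sometimes computed on the log
scale, the transformed-scale R² is kept alongside (`r2_transformed`).
Adjusted R² uses `1 − (1 − R²)(n − 1)/(n − 2)` (two fitted constants).

SE is implemented as the root of the mean squared error — the division by n
sits under the radical — because it is reported in g m⁻², which forces the
root. MEC is `100·mean(|y − y′|/y)`, in percent; a zero measured value is an
error, never silently skipped.

Family selection: maximum training R², ties broken by minimum test SE.
Unfittable families (a log of a nonpositive value) are recorded as failures
and excluded, not fatal.

The campaign splits 173 quadrats into 153 model-building + 20 hold-out, and
the model group into 115 train + 38 test, by uniform random partition under
a seed; other campaign sizes scale these proportions.

## Cross-calibration and composition

The regression direction is fixed: ground NDVI on satellite NDVI, because
that is the direction substituted into the ground model. The composite
stores the four parent constants (provenance) rather than the reduced
two-constant form `a·e^(b·d) · e^(b·c·t)`; tests require the two evaluations
to agree to 1e-12 relative. Only the exponential family composes; requesting
composition with another family is an error. Evaluation outside NDVI
[−1, 1] is a domain error.

## Rasters

Rasters are single-band float64 grids with a north-up affine geotransform,
a nodata sentinel (default −9999) and an EPSG tag, written and read as
GeoTIFF through tifffile using the standard geo tags; rotation and
reprojection are out of scope. Cell (0, 0) is top-left; cells are half-open
intervals and point extraction takes the containing cell (floor of the
inverse geotransform) with no interpolation. Inversion propagates nodata,
turns out-of-range NDVI cells into nodata with a logged count, and flags —
does not clamp — predictions above the saturation threshold (default
250 g m⁻², where NDVI loses sensitivity in dense canopies). Points on
nodata pixels or outside the grid produce per-point status entries.

## Synthetic campaign generator

The generator emulates the survey design the analysis assumes: 39 plots,
173 quadrats (allocated 17 × 5 + 22 × 4; real per-plot counts are unknown),
ground law a = 12.523 g m⁻², b = 3.370, calibration c = 0.462, d = 0.413,
biomass CV 0.2.

Choices the design left open, fixed here once:

* **Spectra** are linear mixtures of two idealized endmembers — vegetation
  with a chlorophyll red absorption, a logistic red edge near 718 nm and an
  NIR plateau (NDVI ≈ 0.89); soil as a gently rising line (NDVI ≈ 0.10) —
  on a 400–1000 nm, 2.3 nm grid, plus additive reflectance noise
  (sd 0.005). Only the band-window means matter downstream.
* **Cover structure**: plot-level cover means uniform on [0.20, 0.85];
  quadrat cover scatters around its plot mean with sd 0.08, clipped to
  [0, 1]. This yields quadrat NDVI ≈ 0.25–0.90 and keeps the implied
  satellite NDVI inside [−1, 1].
* **Biomass noise is multiplicative** (`AGB = a·e^(b·NDVI)·(1 + ε)`,
  ε ~ N(0, CV), floored at 1 g m⁻²): an exponential mean with additive
  constant noise would go negative at low NDVI, and field biomass spread is
  heteroscedastic. Biomass is generated from the quadrat's *realized* NDVI
  (computed from its simulated spectrum), so the zero-noise pipeline
  round-trips the generator constants exactly.
* **Satellite NDVI** is the inverse calibration of the plot-mean ground
  NDVI plus additive noise (sd 0.02), clipped to [−1, 1]. The sd is kept
  small because the noise enters the regressor of the calibration fit;
  large regressor noise would attenuate the recovered slope and the
  generator is meant to be recoverable. Consequently the synthetic
  cross-calibration is much tighter (R² ≈ 0.99) than real multi-sensor
  scatter, and the hold-out validation errors are correspondingly
  optimistic relative to a real campaign.
* **Raster**: 50 × 50 cells of 30 m, one pixel per plot (sampled without
  replacement), nodata elsewhere — a desk-scale stand-in for a full
  satellite scene.

What passing tests on this generator show: the fitting, composition, raster
and validation machinery is correct, deterministic under seeds, and recovers
known parameters at the stated noise. What they do not show: robustness to
real-data pathologies — mixed vegetation types, atmospheric residuals,
geolocation error between plot and pixel, within-pixel heterogeneity beyond
the quadrat sample, or NDVI saturation structure beyond the simple
exponential law.

## Numerical notes

* CSV outputs use 12-significant-digit formatting; GeoTIFF writes are
  byte-deterministic, so identical config + seed reproduces identical files.
* All seeds feed `numpy.random.default_rng`; the pipeline seed drives the
  data split, and the campaign seed (defaulting to it) drives generation.
* Problem sizes in the routine checks — campaigns of 39 plots / 173
  quadrats, sweeps of 100–200 campaigns, rasters up to 50 × 50 — were chosen
  as the smallest sizes at which the survey-scale statistics are stable.

## Known limitations

Single-date, single-stratum, single-sensor; no error propagation through
the two regression stages (a composite prediction interval would need it);
no reprojection; the cross-calibration is fitted on quadrat-mean plot NDVI,
the only ground truth available, though a real pixel averages the whole
plot.
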