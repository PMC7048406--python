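"""Cross-sensor NDVI calibration and model composition.

A field spectrometer and a satellite sensor see the same canopy through
different bands, footprints and atmospheres, so their NDVIs differ
systematically. At plot level (one 30 x 30 m plot = one satellite pixel) the
relationship is taken as linear,

    SOC_NDVI = c * TM_NDVI + d,

fitted by OLS of ground NDVI on satellite NDVI — that direction, not the
inverse, because the calibration is substituted into the ground biomass model

    AGB = a * e**(b * SOC_NDVI)

to give the composite satellite inversion model

    AGB(t) = a * e**(b * (c*t + d)).

The composite keeps the four parent constants (provenance) rather than the
algebraically reduced two-constant form; both evaluations must agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateModelError, DomainError
from .regress import RegressionFit


@dataclass(frozen=True)
class CrossCalibration:
    """Plot-level linear map from satellite NDVI to ground NDVI."""

    slope: float  # c
    intercept: float  # d
    n: int
    r2: float

    def predict(self, tm_ndvi):
        return self.slope * np.asarray(tm_ndvi, dtype=float) + self.intercept


def fit_cross_calibration(
    plots: Union[pd.DataFrame, Sequence[float]],
    soc_ndvi=None,
    tm_col: str = "tm_ndvi",
    soc_col: str = "soc_ndvi_mean",
) -> CrossCalibration:
    """OLS of plot-mean ground NDVI on satellite NDVI.

    Accepts either a plot table (columns ``tm_ndvi``, ``soc_ndvi_mean``) or
    two arrays ``(tm_ndvi, soc_ndvi)``.
    """
    if isinstance(plots, pd.DataFrame):
        tm = plots[tm_col].to_numpy(float)
        soc = plots[soc_col].to_numpy(float)
    else:
        tm = np.asarray(plots, dtype=float)
        soc = np.asarray(soc_ndvi, dtype=float)
    if tm.shape != soc.shape or tm.ndim != 1:
        raise ValueError("tm_ndvi and soc_ndvi must be 1-d arrays of equal length")
    if tm.size < 3:
        raise ValueError(f"need >= 3 plots, got {tm.size}")
    if np.ptp(tm) == 0:
        raise DegenerateModelError("tm_ndvi has zero variance; calibration slope undefined")
    res = stats.linregress(tm, soc)
    return CrossCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(tm.size),
        r2=float(res.rvalue**2),
    )


@dataclass(frozen=True)
class CompositeModel:
    """The satellite biomass inversion model AGB(t) = a * e**(b*(c*t + d)).

    ``a`` (g m^-2) and ``b`` come from the exponential ground fit of AGB on
    ground NDVI; ``c`` and ``d`` from the plot-level cross-calibration of
    ground NDVI on satellite NDVI ``t``.
    """

    a: float
    b: float
    c: float
    d: float
    ground_r2: Optional[float] = None
    cross_r2: Optional[float] = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")

    def evaluate(self, tm_ndvi):
        """Biomass (g m^-2) at satellite NDVI ``tm_ndvi`` (scalar or array)."""
        t = np.asarray(tm_ndvi, dtype=float)
        if np.any((t < -1.0) | (t > 1.0)):
            raise DomainError("tm_ndvi outside [-1, 1]")
        out = self.a * np.exp(self.b * (self.c * t + self.d))
        return float(out) if np.isscalar(tm_ndvi) else out

    def reduced_form(self) -> Tuple[float, float]:
        """Equivalent two-constant form (a', b') with AGB(t) = a' * e**(b'*t)."""
        return self.a * float(np.exp(self.b * self.d)), self.b * self.c

    def equation(self) -> str:
        return f"AGB = {self.a:.3f} x e^({self.b:.3f} x ({self.c:.3f} x TM_NDVI + {self.d:.3f}))"

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "ground_r2": self.ground_r2,
            "cross_r2": self.cross_r2,
            "equation": self.equation(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CompositeModel":
        return cls(
            a=payload["a"],
            b=payload["b"],
            c=payload["c"],
            d=payload["d"],
            ground_r2=payload.get("ground_r2"),
            cross_r2=payload.get("cross_r2"),
        )


def compose(ground: RegressionFit, cross: CrossCalibration) -> CompositeModel:
    """Substitute the cross-calibration into the exponential ground model.

    Only the exponential family composes into the closed form above; other
    families raise.
    """
    if ground.family != "exponential":
        raise DomainError(
            f"composition requires an exponential ground fit, got {ground.family!r}"
        )
    return CompositeModel(
        a=ground.coef_a,
        b=ground.coef_b,
        c=cross.slope,
        d=cross.intercept,
        ground_r2=ground.r2,
        cross_r2=cross.r2,
    )
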