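"""Accuracy assessment of predicted vs measured biomass at hold-out points.

Pairs of (measured, predicted) biomass are summarized by the same two error
statistics used in family comparison — SE (root mean squared error, g m^-2)
and MEC (mean absolute relative error, %) — plus the OLS line and R² of
predicted on measured. Missing predictions (points that fell on nodata
pixels or outside the raster) are excluded pairwise with a logged count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .regress import mec, standard_error

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationReport:
    """Hold-out accuracy of the inversion model."""

    n: int
    se: float  # g m^-2
    mec: float  # percent
    slope: float
    intercept: float
    r2: float
    n_excluded: int
    pairs: pd.DataFrame  # columns: actual, predicted

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "se_g_m2": self.se,
            "mec_percent": self.mec,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n_excluded": self.n_excluded,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def validate(actual: Sequence[float], predicted: Sequence[float]) -> ValidationReport:
    """Compare measured and predicted biomass at hold-out locations.

    NaN predictions are dropped pairwise (logged). Requires >= 2 surviving
    pairs and strictly positive measured values (MEC divides by them).
    """
    y = np.asarray(actual, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.shape != yp.shape or y.ndim != 1:
        raise ValueError("actual and predicted must be 1-d arrays of equal length")
    keep = np.isfinite(yp) & np.isfinite(y)
    n_excluded = int(y.size - keep.sum())
    if n_excluded:
        logger.warning("%d pair(s) excluded for missing predictions", n_excluded)
    y, yp = y[keep], yp[keep]
    if y.size < 2:
        raise ValueError(f"need >= 2 valid pairs, got {y.size}")
    if np.any(y <= 0):
        raise DomainError("measured biomass must be > 0")
    res = stats.linregress(y, yp)
    return ValidationReport(
        n=int(y.size),
        se=standard_error(y, yp),
        mec=mec(y, yp),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_excluded=n_excluded,
        pairs=pd.DataFrame({"actual": y, "predicted": yp}),
    )


def scatter_plot(report: ValidationReport, path, title: Optional[str] = None) -> None:
    """Predicted-vs-actual scatter with the fitted line and the 1:1 line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    y = report.pairs["actual"].to_numpy()
    yp = report.pairs["predicted"].to_numpy()
    ax.scatter(y, yp, s=25, edgecolor="k", facecolor="0.7")
    lim = [0, max(y.max(), yp.max()) * 1.1]
    ax.plot(lim, lim, "k:", lw=1, label="1:1")
    xs = np.linspace(lim[0] + 1e-9, lim[1], 50)
    ax.plot(xs, report.slope * xs + report.intercept, "k-", lw=1.2,
            label=f"fit (R$^2$={report.r2:.3f})")
    ax.set_xlabel("measured AGB (g m$^{-2}$)")
    ax.set_ylabel("predicted AGB (g m$^{-2}$)")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    ax.annotate(
        f"SE = {report.se:.2f} g m$^{{-2}}$\nMEC = {report.mec:.2f}%\nn = {report.n}",
        xy=(0.05, 0.78), xycoords="axes fraction",
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
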