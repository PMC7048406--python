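"""Regression-family comparison for AGB vs ground NDVI.

Fits the four empirical families conventionally offered by spreadsheet
trendlines,

    linear       y = a*x + b
    logarithmic  y = a*ln(x) + b
    power        y = a*x**b        (OLS of ln y on ln x)
    exponential  y = a*e**(b*x)    (OLS of ln y on x)

and compares them by the coefficient of determination on the original
response scale, plus two prediction-error statistics on held-out quadrats:

    SE  = sqrt( sum (y - y')^2 / n )       root mean squared error, g m^-2
    MEC = 100 * mean( |y - y'| / y )       mean absolute relative error, %

Power and exponential coefficients come from log-linearized ordinary least
squares — the convention behind printed trendline equations — which is
deterministic; an optional nonlinear least-squares refinement is available
behind ``refine=True``. R² is reported on the original scale
(1 - SS_res/SS_tot with back-transformed predictions); for log-linearized
families the R² of the transformed fit is kept alongside as ``r2_transformed``
because published values may be on either scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateModelError, DomainError

FAMILIES = ("linear", "logarithmic", "power", "exponential")

#: Column names of the canonical quadrat table.
QUADRAT_COLUMNS = ("quadrat_id", "plot_id", "soc_ndvi", "agb_g_m2")


@dataclass(frozen=True)
class RegressionFit:
    """A fitted two-parameter family with its goodness-of-fit statistics."""

    family: str
    coef_a: float
    coef_b: float
    n: int
    r2: float
    adj_r2: float
    #: R² of the log-linearized OLS for power/exponential families, else None.
    r2_transformed: Optional[float] = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a, b = self.coef_a, self.coef_b
        if self.family == "linear":
            return a * x + b
        if self.family == "logarithmic":
            return a * np.log(x) + b
        if self.family == "power":
            return a * np.power(x, b)
        if self.family == "exponential":
            return a * np.exp(b * x)
        raise ValueError(f"unknown family {self.family!r}")

    def equation(self) -> str:
        a, b = self.coef_a, self.coef_b
        return {
            "linear": f"y = {a:.3f}x {'+' if b >= 0 else '-'} {abs(b):.3f}",
            "logarithmic": f"y = {a:.3f}ln(x) {'+' if b >= 0 else '-'} {abs(b):.3f}",
            "power": f"y = {a:.3f}x^{b:.3f}",
            "exponential": f"y = {a:.3f}e^{b:.3f}x",
        }[self.family]


@dataclass(frozen=True)
class FitMetrics:
    """Held-out prediction errors of one family."""

    se: float  # g m^-2
    mec: float  # percent


@dataclass(frozen=True)
class DataSplit:
    """The two nested random partitions of the quadrat campaign.

    The full campaign splits into a model-building group and an independent
    hold-out group; the model group splits again into train (family fitting)
    and test (family error comparison) subsets.
    """

    model_ids: Tuple
    holdout_ids: Tuple
    train_ids: Tuple
    test_ids: Tuple
    seed: int

    def __post_init__(self):
        model, hold = set(self.model_ids), set(self.holdout_ids)
        train, test = set(self.train_ids), set(self.test_ids)
        if model & hold:
            raise ValueError("model and holdout groups overlap")
        if train & test:
            raise ValueError("train and test subsets overlap")
        if train | test != model:
            raise ValueError("train/test must partition the model group")


def split_data(
    quadrat_ids: Sequence,
    sizes: Tuple[int, int, int] = (153, 20, 115),
    seed: int = 0,
) -> DataSplit:
    """Random nested partition of quadrat ids, reproducible under ``seed``.

    ``sizes = (model_n, holdout_n, train_n)``: model_n + holdout_n must equal
    the number of quadrats and train_n <= model_n; the test subset is the
    remainder of the model group.
    """
    ids = list(quadrat_ids)
    model_n, holdout_n, train_n = sizes
    if len(set(ids)) != len(ids):
        raise ValueError("quadrat ids must be unique")
    if model_n + holdout_n != len(ids):
        raise ValueError(
            f"sizes {sizes}: model_n + holdout_n = {model_n + holdout_n} "
            f"!= {len(ids)} quadrats"
        )
    if train_n > model_n:
        raise ValueError(f"train_n ({train_n}) exceeds model_n ({model_n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    model = shuffled[:model_n]
    holdout = shuffled[model_n:]
    return DataSplit(
        model_ids=tuple(model),
        holdout_ids=tuple(holdout),
        train_ids=tuple(model[:train_n]),
        test_ids=tuple(model[train_n:]),
        seed=seed,
    )


def _require_positive(values: np.ndarray, name: str, family: str) -> None:
    bad = np.nonzero(values <= 0)[0]
    if bad.size:
        raise DomainError(
            f"{family} fit requires {name} > 0; offending indices: {bad[:10].tolist()}"
        )


def _r2_original_scale(y: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateModelError("response has zero variance; R^2 undefined")
    return 1.0 - ss_res / ss_tot


def fit_family(
    x: Sequence[float],
    y: Sequence[float],
    family: str,
    refine: bool = False,
) -> RegressionFit:
    """Fit one family by OLS (log-linearized where the form requires it).

    Parameters
    ----------
    x, y : regressor (NDVI, unitless) and response (AGB, g m^-2).
    family : one of linear, logarithmic, power, exponential.
    refine : if True, polish power/exponential coefficients by nonlinear
        least squares started from the log-linear solution.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")

    r2_transformed = None
    if family == "linear":
        res = stats.linregress(x, y)
        a, b = float(res.slope), float(res.intercept)
    elif family == "logarithmic":
        _require_positive(x, "x", family)
        res = stats.linregress(np.log(x), y)
        a, b = float(res.slope), float(res.intercept)
    elif family == "power":
        _require_positive(x, "x", family)
        _require_positive(y, "y", family)
        res = stats.linregress(np.log(x), np.log(y))
        a, b = float(np.exp(res.intercept)), float(res.slope)
        r2_transformed = float(res.rvalue**2)
    else:  # exponential
        _require_positive(y, "y", family)
        res = stats.linregress(x, np.log(y))
        a, b = float(np.exp(res.intercept)), float(res.slope)
        r2_transformed = float(res.rvalue**2)

    if refine and family in ("power", "exponential"):
        f = (lambda x_, a_, b_: a_ * np.power(x_, b_)) if family == "power" else (
            lambda x_, a_, b_: a_ * np.exp(b_ * x_)
        )
        (a, b), _ = optimize.curve_fit(f, x, y, p0=(a, b), maxfev=10000)
        a, b = float(a), float(b)

    fit = RegressionFit(family, a, b, n, r2=0.0, adj_r2=0.0, r2_transformed=r2_transformed)
    r2 = _r2_original_scale(y, fit.predict(x))
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionFit(family, a, b, n, r2=r2, adj_r2=adj, r2_transformed=r2_transformed)


def standard_error(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """Root mean squared prediction error, sqrt(sum (y - y')^2 / n), g m^-2."""
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if y.shape != yp.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yp.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y - yp) ** 2)))


def mec(y: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean error coefficient, 100 * mean(|y - y'| / y), in percent."""
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if y.shape != yp.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yp.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if np.any(y == 0):
        raise DomainError("MEC undefined: measured value y = 0 present")
    return float(100.0 * np.mean(np.abs((y - yp) / y)))


@dataclass
class FamilyComparison:
    """Side-by-side fits and hold-out errors of the candidate families."""

    fits: Dict[str, RegressionFit]
    metrics: Dict[str, FitMetrics]
    selected: str
    failures: Dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Families as columns; equation, n, r2, adj_r2, SE, MEC as rows."""
        cols = {}
        for fam in FAMILIES:
            if fam in self.fits:
                f, m = self.fits[fam], self.metrics[fam]
                cols[fam] = {
                    "equation": f.equation(),
                    "n": f.n,
                    "r2": f.r2,
                    "adj_r2": f.adj_r2,
                    "se_g_m2": m.se,
                    "mec_percent": m.mec,
                }
            else:
                cols[fam] = {"equation": f"failed: {self.failures[fam]}"}
        return pd.DataFrame(cols)


def compare_families(
    train: pd.DataFrame,
    test: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    x_col: str = "soc_ndvi",
    y_col: str = "agb_g_m2",
) -> FamilyComparison:
    """Fit each family on ``train``, score on ``test``, select the best.

    Selection: maximum training R² (original scale); ties broken by minimum
    test SE. Families that cannot be fitted (log of a nonpositive value) are
    recorded under ``failures`` and excluded from selection.
    """
    fits: Dict[str, RegressionFit] = {}
    metrics: Dict[str, FitMetrics] = {}
    failures: Dict[str, str] = {}
    xt, yt = train[x_col].to_numpy(float), train[y_col].to_numpy(float)
    xv, yv = test[x_col].to_numpy(float), test[y_col].to_numpy(float)
    for fam in families:
        try:
            f = fit_family(xt, yt, fam)
            pred = f.predict(xv)
            metrics[fam] = FitMetrics(se=standard_error(yv, pred), mec=mec(yv, pred))
            fits[fam] = f
        except (DomainError, DegenerateModelError) as exc:
            failures[fam] = str(exc)
    if not fits:
        raise DegenerateModelError("no family could be fitted")
    selected = max(fits, key=lambda fam: (fits[fam].r2, -metrics[fam].se))
    return FamilyComparison(fits=fits, metrics=metrics, selected=selected, failures=failures)
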