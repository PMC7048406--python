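"""Recompute the published summary statistics from the study's deposited tables.

The original campaign's deposited data come as three tables:

* S1 — quadrat biomass and ground NDVI (the regression analysis data), with
  an optional ``group`` column marking the train/test membership of each
  quadrat;
* S2 — plot-level satellite NDVI and ground NDVI pairs;
* S3 — actual and predicted biomass at the hold-out test points.

Given CSV exports of those tables this module re-runs the package's own
fitting and validation code on them and returns every headline statistic:
the exponential ground-model coefficients and R², the hold-out SE/MEC of
each family, the cross-calibration slope/intercept/R², and the final
validation SE/MEC. Column names are matched case-insensitively against a
small set of aliases because deposited spreadsheets rarely share a schema.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from .crosscal import fit_cross_calibration
from .regress import FAMILIES, fit_family, mec, standard_error
from .validate import validate

_ALIASES = {
    "soc_ndvi": ("soc_ndvi", "socndvi", "ndvi", "soc ndvi", "x"),
    "agb_g_m2": ("agb_g_m2", "agb", "biomass", "anpp", "y"),
    "tm_ndvi": ("tm_ndvi", "tmndvi", "tm ndvi"),
    "soc_ndvi_mean": ("soc_ndvi_mean", "soc_ndvi", "socndvi", "soc ndvi"),
    "actual": ("actual", "actual_agb", "measured", "observed", "actual biomass"),
    "predicted": ("predicted", "predicted_agb", "estimated", "predicted biomass"),
    "group": ("group", "set", "role"),
}


def _find_column(df: pd.DataFrame, key: str, required: bool = True) -> Optional[str]:
    normalized = {str(c).strip().lower(): c for c in df.columns}
    for alias in _ALIASES[key]:
        if alias in normalized:
            return normalized[alias]
    if required:
        raise KeyError(f"no column matching {key!r} among {list(df.columns)}")
    return None


def reproduce_reference_statistics(
    s1_csv, s2_csv, s3_csv, families: Sequence[str] = FAMILIES
) -> Dict[str, float]:
    """Recompute every published headline number from the deposited tables.

    Returns a flat dict: per-family ``{family}_a/_b/_r2/_adj_r2`` (and
    ``_r2_log`` for the log-linearized families) fitted on the train rows of
    S1, ``{family}_se/_mec`` on its test rows (when a group column marks
    them; otherwise fitting uses all rows and errors are omitted),
    ``cross_slope/cross_intercept/cross_r2/cross_n`` from S2, and
    ``validation_se/validation_mec/validation_r2/validation_n`` from S3.
    """
    out: Dict[str, float] = {}

    s1 = pd.read_csv(Path(s1_csv))
    x_col = _find_column(s1, "soc_ndvi")
    y_col = _find_column(s1, "agb_g_m2")
    group_col = _find_column(s1, "group", required=False)
    if group_col is not None:
        groups = s1[group_col].astype(str).str.strip().str.lower()
        train = s1[groups.isin(("train", "model", "build"))]
        test = s1[groups.isin(("test",))]
    else:
        train, test = s1, None
    for fam in families:
        fit = fit_family(train[x_col].to_numpy(float), train[y_col].to_numpy(float), fam)
        out[f"{fam}_a"] = fit.coef_a
        out[f"{fam}_b"] = fit.coef_b
        out[f"{fam}_r2"] = fit.r2
        out[f"{fam}_adj_r2"] = fit.adj_r2
        if fit.r2_transformed is not None:
            out[f"{fam}_r2_log"] = fit.r2_transformed
        if test is not None and len(test):
            pred = fit.predict(test[x_col].to_numpy(float))
            out[f"{fam}_se"] = standard_error(test[y_col].to_numpy(float), pred)
            out[f"{fam}_mec"] = mec(test[y_col].to_numpy(float), pred)
    out["ground_n"] = float(len(train))

    s2 = pd.read_csv(Path(s2_csv))
    cross = fit_cross_calibration(
        s2, tm_col=_find_column(s2, "tm_ndvi"), soc_col=_find_column(s2, "soc_ndvi_mean")
    )
    out["cross_slope"] = cross.slope
    out["cross_intercept"] = cross.intercept
    out["cross_r2"] = cross.r2
    out["cross_n"] = float(cross.n)

    s3 = pd.read_csv(Path(s3_csv))
    report = validate(
        s3[_find_column(s3, "actual")].to_numpy(float),
        s3[_find_column(s3, "predicted")].to_numpy(float),
    )
    out["validation_se"] = report.se
    out["validation_mec"] = report.mec
    out["validation_r2"] = report.r2
    out["validation_n"] = float(report.n)
    return out
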