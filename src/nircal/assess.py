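"""Calibration and validation statistics for NIR models.

Conventions (all concentrations in mg/kg):

* RMSE uses the plain ``n`` denominator: RMSEC on calibration residuals,
  RMSECV pooled over cross-validation folds, RMSEP on external errors.
* R-squared is the squared Pearson correlation between measured and
  predicted values (the usual NIR reporting convention); the 1 - SSE/SST
  variant is also computed for reference.
* RPD = SD(reference values) / RMSECV internally, or SD / RMSEP(C)
  externally; > 2 indicates a good calibration, < 1.5 a poor one.
* RMSEP(C) is the bias-corrected standard error of prediction,
  sqrt(sum((e - bias)^2) / (n - 1)), so RMSEP^2 = bias^2 + RMSEP(C)^2*(n-1)/n.
* The model-applicability bounds of a calibration are Est.Min =
  max(0, mean - 3*SD) and Est.Max = mean + 3*SD of the calibration
  reference values; an external-validation summary reports the min/max of
  the predicted values instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationSummary",
    "ExternalValidationSummary",
    "CorrelationResult",
    "rmse",
    "r_squared",
    "rpd",
    "estimation_bounds",
    "calibration_summary",
    "external_validate",
    "correlation_matrix",
    "rounded",
    "ratio_interval",
    "rpd_consistent",
]


def rmse(errors) -> float:
    """Root mean square error with the plain n denominator."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("empty error vector")
    return float(np.sqrt(np.mean(e ** 2)))


def r_squared(y, y_hat) -> float:
    """Squared Pearson correlation between measured and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.std() <= 0:
        raise ValueError("reference values have zero variance")
    if y_hat.std() <= 0:
        warnings.warn("predictions have zero variance; R^2 set to 0")
        return 0.0
    return float(np.corrcoef(y, y_hat)[0, 1] ** 2)


def rpd(sd_ref: float, rmse_value: float) -> float:
    """Ratio of performance to deviation: SD of the reference method over
    RMSECV (internal) or RMSEP(C) (external)."""
    if rmse_value <= 0:
        raise ValueError("RPD undefined for non-positive error")
    return float(sd_ref) / float(rmse_value)


def estimation_bounds(mean: float, sd: float) -> tuple[float, float]:
    """Model-applicability bounds: (max(0, mean - 3 SD), mean + 3 SD)."""
    return max(0.0, mean - 3.0 * sd), mean + 3.0 * sd


@dataclass
class CalibrationSummary:
    """One row of a calibration table (internal cross-validation)."""

    element: str
    treatment: str
    n: int
    mean: float
    sd: float
    est_min: float
    est_max: float
    rmsec: float
    r2: float
    rmsecv: float
    rpd: float
    n_factors: int = 0
    r2_fit: float = float("nan")  # 1 - SSE/SST on the calibration fit

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExternalValidationSummary:
    """One row of an external-validation table."""

    element: str
    n: int
    mean: float
    sd: float
    est_min: float
    est_max: float
    rmsep: float
    bias: float
    rmsep_c: float
    rpd: float

    def to_dict(self) -> dict:
        return asdict(self)


def calibration_summary(element, treatment, y, fitted, cv_predictions, rmsecv,
                        n_factors: int = 0) -> CalibrationSummary:
    """Assemble the calibration summary for the surviving samples.

    ``fitted`` are in-model predictions (for RMSEC); ``cv_predictions`` the
    grouped cross-validation predictions (for the headline R^2).
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    mean = float(y.mean())
    sd = float(y.std(ddof=1))
    est_min, est_max = estimation_bounds(mean, sd)
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - mean) ** 2).sum())
    return CalibrationSummary(
        element=str(element),
        treatment=str(treatment),
        n=int(y.size),
        mean=mean,
        sd=sd,
        est_min=est_min,
        est_max=est_max,
        rmsec=rmse(y - fitted),
        r2=r_squared(y, cv_predictions),
        rmsecv=float(rmsecv),
        rpd=rpd(sd, rmsecv),
        n_factors=int(n_factors),
        r2_fit=1.0 - sse / sst if sst > 0 else float("nan"),
    )


def external_validate(y_true, y_pred, element: str = "") -> ExternalValidationSummary:
    """External-validation statistics from reference and predicted values.

    e = prediction - reference; bias = mean(e); RMSEP = sqrt(mean(e^2));
    RMSEP(C) = sqrt(sum((e - bias)^2)/(n-1)); RPD = SD(reference)/RMSEP(C).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 3:
        raise ValueError("external validation needs at least 3 samples")
    e = y_pred - y_true
    bias = float(e.mean())
    rmsep = rmse(e)
    rmsep_c = float(np.sqrt(((e - bias) ** 2).sum() / (e.size - 1)))
    sd = float(y_true.std(ddof=1))
    return ExternalValidationSummary(
        element=str(element),
        n=int(y_true.size),
        mean=float(y_true.mean()),
        sd=sd,
        est_min=float(y_pred.min()),
        est_max=float(y_pred.max()),
        rmsep=rmsep,
        bias=bias,
        rmsep_c=rmsep_c,
        rpd=rpd(sd, rmsep_c) if rmsep_c > 0 else float("inf"),
    )


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(reference, min_pairs: int = 3) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between element columns.

    Below-LOQ cells are treated as missing.  Cells with fewer than
    ``min_pairs`` complete pairs are flagged missing (NaN).
    """
    if isinstance(reference, pd.DataFrame):
        values = reference
    elif hasattr(reference, "values") and isinstance(reference.values, pd.DataFrame):
        values = reference.values
    else:
        values = pd.DataFrame(reference)
    cols = list(values.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = values[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) >= min_pairs:
                if i == j:
                    r[i, j], p[i, j] = 1.0, 0.0
                else:
                    res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
                    r[i, j] = r[j, i] = res.statistic
                    p[i, j] = p[j, i] = res.pvalue
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols),
    )


# ---------------------------------------------------------------------------
# printed-table consistency helpers


def rounded(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed tables."""
    factor = 10.0 ** decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


def ratio_interval(num: float, den: float, decimals: int = 1) -> tuple[float, float]:
    """Interval of ratios achievable when numerator and denominator are only
    known to the given printed precision."""
    h = 0.5 * 10.0 ** -decimals
    return (num - h) / (den + h), (num + h) / (den - h)


def rpd_consistent(sd: float, error: float, printed_rpd: float, decimals: int = 1) -> bool:
    """Whether a printed RPD is arithmetically consistent with the printed SD
    and error cells, allowing for the rounding of every cell."""
    lo, hi = ratio_interval(sd, error, decimals)
    h = 0.5 * 10.0 ** -decimals
    return lo <= printed_rpd + h and hi >= printed_rpd - h
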