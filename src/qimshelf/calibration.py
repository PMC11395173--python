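"""Straight-line calibration of QI (or any spoilage indicator) on storage days.

The sensory quality index of ice-stored fish rises close to linearly with
days in ice, so a two-parameter line QI = slope*day + intercept calibrates
storage time. Inverse prediction then reads an unknown day-in-ice off an
observed QI, which is what makes the method useful on fish of unknown
history: equivalent storage day and remaining shelf-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class CalibrationError(ValueError):
    """Raised on degenerate calibration inputs (n < 2, constant x, zero slope)."""


@dataclass(frozen=True)
class LinearFit:
    """An ordinary-least-squares straight line with its fit diagnostics.

    residual_sd is the root mean squared residual with n-2 denominator
    (response units); r_squared is 1 - SSres/SStot.
    """

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int

    def predict(self, day: float) -> float:
        return self.slope * day + self.intercept


@dataclass(frozen=True)
class DayEstimate:
    """Inverse-prediction result: point estimate of days in ice with an
    approximate (delta-method) confidence interval, clipped at 0."""

    point: float
    lower: float
    upper: float
    confidence: float


def fit_line(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS fit by closed-form normal equations.

    Raises CalibrationError for n < 2 or zero-variance x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 2:
        raise CalibrationError("need at least 2 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise CalibrationError("x has zero variance; line is not identifiable")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean()) - slope * float(x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant y: the flat line fits exactly
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    residual_sd = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    return LinearFit(
        slope=slope,
        intercept=intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        residual_sd=residual_sd,
        n=n,
    )


def _round_half_away(value: float) -> int:
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def predict_qi(fit: LinearFit, day: float, protocol_max: int) -> int:
    """Integer QI predicted at a storage day: evaluate the line, round
    half-away-from-zero, clamp to [0, protocol_max]."""
    if day < 0:
        raise CalibrationError("storage day must be >= 0")
    raw = fit.predict(day)
    return max(0, min(protocol_max, _round_half_away(raw)))


def inverse_predict(
    fit: LinearFit, qi: float, confidence: float = 0.95
) -> DayEstimate:
    """Equivalent day of storage for an observed QI.

    Point estimate (qi - intercept)/slope; the interval propagates the
    calibration residual SD through the inverse map to first order
    (delta method): point +/- z * residual_sd/|slope|. Adequate whenever the
    slope is many standard errors from zero, as in practice for QIM lines;
    it is an approximation, not a Fieller interval. Bounds are clipped at 0
    (negative storage days are meaningless).
    """
    if fit.slope == 0.0:
        raise CalibrationError("calibration uninformative: slope is zero")
    if not 0.0 < confidence < 1.0:
        raise CalibrationError("confidence must be in (0, 1)")
    point = (qi - fit.intercept) / fit.slope
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    half = z * fit.residual_sd / abs(fit.slope)
    return DayEstimate(
        point=max(0.0, point),
        lower=max(0.0, point - half),
        upper=max(0.0, point + half),
        confidence=confidence,
    )


def remaining_shelf_life(fit: LinearFit, qi: float, shelf_life_days: float) -> float:
    """Days of acceptability left: shelf-life minus the equivalent storage
    day, floored at 0."""
    if fit.slope <= 0.0:
        raise CalibrationError("remaining shelf-life needs an increasing calibration")
    est = inverse_predict(fit, qi)
    return max(0.0, shelf_life_days - est.point)


def sep(observed: Sequence[float], predicted: Sequence[float]) -> dict[str, float]:
    """Prediction-error summaries for a calibration model.

    Conventions for the "standard error of performance" differ across the
    chemometrics literature, so all three are reported:

    - bias: mean(predicted - observed)
    - rmsep: root mean squared prediction error
    - sep_corrected: bias-corrected SD of the errors (n-1 denominator)

    They satisfy rmsep^2 = bias^2 + sep_corrected^2 * (n-1)/n.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise CalibrationError("observed and predicted must be 1-D of equal length")
    n = len(obs)
    if n < 2:
        raise CalibrationError("need at least 2 pairs")
    err = pred - obs
    bias = float(err.mean())
    rmsep = float(np.sqrt(np.mean(err**2)))
    sep_c = float(np.sqrt(np.sum((err - bias) ** 2) / (n - 1)))
    return {"rmsep": rmsep, "bias": bias, "sep_corrected": sep_c}
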