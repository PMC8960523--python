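"""Mono-exponential clearance fitting on the late (>= 24 h) washout window."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import DoseRateSeries

__all__ = ["MonoExpFit", "FitError", "fit_monoexponential", "predict_rate"]

LN2 = math.log(2.0)

#: samples within this many hours of the window start still count as in-window
_TIME_TOL_H = 1e-9


class FitError(ValueError):
    """Raised when a series cannot support a mono-exponential fit."""


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted clearance model ``rate(t) = exp(log_amplitude) * exp(-lambda*t)``.

    ``t_eff_h`` is derived from ``rate_lambda`` so the two are consistent by
    construction.  ``r_squared_log`` is the coefficient of determination of
    the underlying log-scale least-squares fit (1.0 for two points).
    """

    rate_lambda: float  # 1/h, > 0
    log_amplitude: float  # ln(rate) extrapolated to t = 0
    fit_window_start_h: float
    n_points: int
    r_squared_log: float

    @property
    def t_eff_h(self) -> float:
        """Effective half-life in hours (= ln 2 / rate_lambda)."""
        return LN2 / self.rate_lambda

    def to_dict(self) -> dict:
        return {
            "rate_lambda": self.rate_lambda,
            "t_eff_h": self.t_eff_h,
            "log_amplitude": self.log_amplitude,
            "fit_window_start_h": self.fit_window_start_h,
            "n_points": self.n_points,
            "r_squared_log": self.r_squared_log,
        }


def fit_monoexponential(
    series: DoseRateSeries, window_start_h: float = 24.0
) -> MonoExpFit:
    """Fit ``ln(rate)`` on time by ordinary least squares over the window.

    Only samples at or after ``window_start_h`` enter the fit.  The slope must
    be negative; the effective half-life is ``ln 2 / (-slope)``.

    Raises
    ------
    FitError
        ``"insufficient points"`` with fewer than two in-window samples,
        ``"non-positive rate"`` if any in-window rate is zero,
        ``"non-decaying series"`` if the fitted slope is >= 0.
    """
    t = np.array(
        [s.time_h for s in series.samples if s.time_h >= window_start_h - _TIME_TOL_H]
    )
    r = np.array(
        [
            s.rate_gy_per_h
            for s in series.samples
            if s.time_h >= window_start_h - _TIME_TOL_H
        ]
    )
    if t.size < 2:
        raise FitError(
            f"insufficient points: {t.size} sample(s) at t >= {window_start_h} h"
        )
    if np.any(r <= 0):
        raise FitError("non-positive rate in fit window")
    log_r = np.log(r)
    slope, intercept = np.polyfit(t, log_r, 1)
    if slope >= 0:
        raise FitError("non-decaying series: fitted slope >= 0")
    resid = log_r - (intercept + slope * t)
    ss_tot = float(np.sum((log_r - log_r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return MonoExpFit(
        rate_lambda=float(-slope),
        log_amplitude=float(intercept),
        fit_window_start_h=float(window_start_h),
        n_points=int(t.size),
        r_squared_log=r2,
    )


def predict_rate(fit: MonoExpFit, time_h: float) -> float:
    """Model dose rate at ``time_h`` (Gy/h); ``time_h`` must be >= 0."""
    if time_h < 0:
        raise ValueError(f"time must be >= 0, got {time_h}")
    return math.exp(fit.log_amplitude - fit.rate_lambda * time_h)
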