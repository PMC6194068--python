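"""Fit statistics and regional calibration of the Hargreaves model.

The Hargreaves formula estimates ET0 from temperature and extraterrestrial
radiation alone, which makes it attractive wherever humidity, wind or
radiation records are unreliable — but its global coefficients
(K = 0.0023, n = 0.5, Toff = 17.8) drift from region to region. Calibration
refits (K, n, Toff) per station by nonlinear least squares against daily
FAO-56 Penman-Monteith ET0 computed from the full weather record, starting
from the global values.

Fit quality is summarised by the squared Pearson correlation R², the root
mean square error, and the absolute relative error of totals (percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from wheatwater.et0 import HargreavesParams, et0_penman_monteith
from wheatwater.radiation import extraterrestrial_radiation
from wheatwater.weatherio import (
    DailyWeatherRecord,
    SiteMetadata,
    day_of_year,
    days_in_year,
)

__all__ = [
    "FitStats",
    "CalibrationResult",
    "r_squared",
    "rmse",
    "absolute_relative_error",
    "fit_hargreaves",
    "calibrate_hargreaves",
    "HARGREAVES_BOUNDS",
]

#: Box bounds for (K, n_exp, T_off) during calibration.
HARGREAVES_BOUNDS = ((1e-6, 1e-6, 0.0), (0.05, 1.5, 50.0))

_MIN_CALIBRATION_DAYS = 60


@dataclass(frozen=True)
class FitStats:
    """R² (0-1), RMSE (units of the compared series), and absolute relative
    error of the series totals (percent)."""

    r2: float
    rmse: float
    are: float

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.are < 0:
            raise ValueError("rmse and are must be nonnegative")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError("r2 must be in [0, 1]")


@dataclass(frozen=True)
class CalibrationResult:
    params: HargreavesParams
    stats: FitStats
    n_days: int
    converged: bool
    iterations: int
    residual_std_error: float  # RMSE * sqrt(n / (n - 3)), 3 fitted params


def r_squared(sim: Sequence[float], obs: Sequence[float]) -> float:
    """Coefficient of determination as the squared sample correlation.

    Affine-invariant: any sim = a*obs + b with a != 0 scores exactly 1.
    Constant series leave the correlation undefined and raise.
    """
    p = np.asarray(sim, dtype=float)
    q = np.asarray(obs, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    dp, dq = p - p.mean(), q - q.mean()
    denom = math.sqrt(float((dq**2).sum() * (dp**2).sum()))
    if denom == 0.0:
        raise ValueError("R^2 undefined for a constant series")
    r = float((dq * dp).sum()) / denom
    return min(1.0, r * r)


def rmse(sim: Sequence[float], obs: Sequence[float]) -> float:
    """Root mean square error between simulated and observed series."""
    p = np.asarray(sim, dtype=float)
    q = np.asarray(obs, dtype=float)
    if p.shape != q.shape or p.size < 1:
        raise ValueError("need two equal-length, non-empty series")
    return float(np.sqrt(np.mean((p - q) ** 2)))


def absolute_relative_error(sim: float, obs: float) -> float:
    """Absolute relative error |sim - obs| / obs * 100 (percent)."""
    if obs == 0:
        raise ValueError("ARE undefined for a zero observation")
    return abs(sim - obs) / abs(obs) * 100.0


def _hs_vector(
    x: np.ndarray, tmax: np.ndarray, tmin: np.ndarray, ra: np.ndarray
) -> np.ndarray:
    k, n, toff = x
    # unfloored form: smooth in the parameters for the solver
    return k / 2.45 * (tmax - tmin) ** n * (0.5 * (tmax + tmin) + toff) * ra


def fit_hargreaves(
    tmax: Sequence[float],
    tmin: Sequence[float],
    ra: Sequence[float],
    target_et0: Sequence[float],
    init: HargreavesParams = HargreavesParams(),
) -> CalibrationResult:
    """Least-squares fit of (K, n, Toff) to a daily ET0 target series.

    Minimises the sum of squared daily residuals HS(params) - target with a
    bounded trust-region solver; deterministic for fixed inputs. Returns
    best-so-far parameters flagged unconverged if the solver hits its
    iteration cap.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    ra = np.asarray(ra, dtype=float)
    target = np.asarray(target_et0, dtype=float)
    if not (tmax.shape == tmin.shape == ra.shape == target.shape):
        raise ValueError("all input series must share one length")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in calibration input")
    # exclude zero-range days: (tmax-tmin)^n has an unbounded n-gradient at 0
    ok = (tmax - tmin) > 1e-9
    tmax, tmin, ra, target = tmax[ok], tmin[ok], ra[ok], target[ok]
    if tmax.size < 2:
        raise ValueError("too few days with nonzero diurnal range")

    x0 = np.array([init.K, init.n_exp, init.T_off])
    result = least_squares(
        lambda x: _hs_vector(x, tmax, tmin, ra) - target,
        x0,
        bounds=HARGREAVES_BOUNDS,
        x_scale=np.array([1e-3, 0.1, 10.0]),
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=500,
    )
    params = HargreavesParams(
        K=float(result.x[0]), n_exp=float(result.x[1]), T_off=float(result.x[2]),
        lambda_=init.lambda_,
    )
    fitted = _hs_vector(result.x, tmax, tmin, ra)
    n = int(target.size)
    stats = FitStats(
        r2=r_squared(fitted, target),
        rmse=rmse(fitted, target),
        are=absolute_relative_error(float(fitted.sum()), float(target.sum()))
        if target.sum() != 0
        else 0.0,
    )
    rse = stats.rmse * math.sqrt(n / (n - 3)) if n > 3 else float("nan")
    return CalibrationResult(
        params=params,
        stats=stats,
        n_days=n,
        converged=bool(result.status > 0),
        iterations=int(result.nfev),
        residual_std_error=rse,
    )


def calibrate_hargreaves(
    weather: Sequence[DailyWeatherRecord],
    site: SiteMetadata,
    init: HargreavesParams = HargreavesParams(),
) -> CalibrationResult:
    """Calibrate Hargreaves against daily Penman-Monteith ET0 for one station.

    Requires at least 60 days carrying the humidity, wind and radiation (or
    sunshine) fields Penman-Monteith needs; radiation absent from a record
    must be filled beforehand (``weatherio.fill_solar_from_sunshine``).
    """
    if len(weather) < _MIN_CALIBRATION_DAYS:
        raise ValueError(
            f"calibration needs >= {_MIN_CALIBRATION_DAYS} days, "
            f"got {len(weather)}"
        )
    tmax = [r.tmax for r in weather]
    tmin = [r.tmin for r in weather]
    ra = [
        extraterrestrial_radiation(
            site.latitude_rad, day_of_year(r.date), days_in_year(r.date.year)
        )
        for r in weather
    ]
    pm = [et0_penman_monteith(r, site) for r in weather]
    return fit_hargreaves(tmax, tmin, ra, pm, init=init)
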