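"""Reference evapotranspiration (ET0) estimators.

Three daily ET0 models for a reference crop surface:

* the DSSAT-style Priestley-Taylor routine — equilibrium evapotranspiration
  from solar radiation and a temperature factor, scaled by a piecewise
  advectivity coefficient alpha(Tmax);
* the FAO-56 Penman-Monteith equation with the standard daily auxiliary
  terms (vapour-pressure slope, psychrometric constant from elevation,
  saturation/actual vapour pressure, net radiation with G = 0);
* the Hargreaves(-Samani) temperature-and-Ra formula with free parameters
  (K, n, Toff) open to regional calibration.

All return mm d-1, floored at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from wheatwater.radiation import (
    daylength,
    extraterrestrial_radiation,
    solar_declination,
    sunset_hour_angle,
)
from wheatwater.weatherio import (
    DailyWeatherRecord,
    SiteMetadata,
    day_of_year,
    days_in_year,
)

__all__ = [
    "HargreavesParams",
    "PTConfig",
    "PMDailyInputs",
    "alpha_advectivity",
    "equilibrium_evapotranspiration",
    "et0_priestley_taylor",
    "et0_penman_monteith",
    "et0_penman_monteith_from_inputs",
    "pm_daily_inputs",
    "et0_hargreaves",
    "saturation_vapor_pressure",
]

logger = logging.getLogger(__name__)

#: Stefan-Boltzmann constant, MJ K-4 m-2 d-1 (FAO-56 daily value).
_SIGMA = 4.903e-9


@dataclass(frozen=True)
class HargreavesParams:
    """Hargreaves coefficients: ET0 = (K/lambda)(Tmax-Tmin)^n (Tmean+Toff) Ra.

    Suggested global values are K = 0.0023, n = 0.5, Toff = 17.8 with latent
    heat lambda = 2.45 MJ kg-1; regional calibration refits (K, n, Toff).
    """

    K: float = 0.0023
    n_exp: float = 0.5
    T_off: float = 17.8
    lambda_: float = 2.45

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0.0 < self.n_exp < 1.5:
            raise ValueError("n_exp must be in (0, 1.5)")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")


@dataclass(frozen=True)
class PTConfig:
    """Priestley-Taylor configuration; albedo defaults to the reference-crop
    value 0.23."""

    albedo: float = 0.23

    def __post_init__(self) -> None:
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError(f"albedo must be in [0, 1], got {self.albedo}")


@dataclass(frozen=True)
class PMDailyInputs:
    """Assembled daily terms of the Penman-Monteith equation."""

    net_radiation: float  # Rn, MJ m-2 d-1
    soil_heat_flux: float  # G, MJ m-2 d-1
    tmean: float  # deg C
    u2: float  # m s-1
    es: float  # kPa
    ea: float  # kPa
    slope: float  # Delta, kPa degC-1
    gamma: float  # kPa degC-1

    def __post_init__(self) -> None:
        if not self.es >= self.ea >= 0.0:
            raise ValueError("need es >= ea >= 0")
        if self.u2 < 0:
            raise ValueError("u2 must be nonnegative")


# ---------------------------------------------------------------------------
# Priestley-Taylor (DSSAT routine)


def alpha_advectivity(tmax: float) -> float:
    """Advectivity coefficient alpha of the DSSAT Priestley-Taylor routine.

    1.1 for Tmax in [5, 35] degC; 0.01 exp(0.18 (Tmax + 20)) below 5 degC;
    1.1 + 0.05 (Tmax - 35) above 35 degC. The cold branch is discontinuous
    at 5 degC (jump from 0.01 e^4.5 ~ 0.900 to 1.1); the warm branch is
    continuous.
    """
    if not math.isfinite(tmax):
        raise ValueError("tmax must be finite")
    if tmax < 5.0:
        return 0.01 * math.exp(0.18 * (tmax + 20.0))
    if tmax > 35.0:
        return 0.05 * (tmax - 35.0) + 1.1
    return 1.1


def equilibrium_evapotranspiration(
    solar_rad: float, tmax: float, tmin: float, config: PTConfig = PTConfig()
) -> float:
    """Equilibrium evapotranspiration EEQ (mm d-1).

    EEQ = SR * (2.04e-4 - 1.83e-4 * albedo) * (0.6 Tmax + 0.4 Tmin + 29).
    Proportional to solar radiation; decreasing in albedo.
    """
    if solar_rad < 0:
        raise ValueError("solar_rad must be nonnegative")
    factor = 0.6 * tmax + 0.4 * tmin + 29.0
    return solar_rad * (2.04e-4 - 1.83e-4 * config.albedo) * factor


def et0_priestley_taylor(
    weather: DailyWeatherRecord, config: PTConfig = PTConfig()
) -> float:
    """Daily ET0 (mm d-1) = alpha(Tmax) * EEQ, floored at zero."""
    if weather.solar_rad is None:
        raise ValueError(
            f"{weather.date}: solar radiation absent; fill it from sunshine "
            "hours via the Angstrom relation first "
            "(weatherio.fill_solar_from_sunshine)"
        )
    eeq = equilibrium_evapotranspiration(
        weather.solar_rad, weather.tmax, weather.tmin, config
    )
    return max(0.0, alpha_advectivity(weather.tmax) * eeq)


# ---------------------------------------------------------------------------
# FAO-56 Penman-Monteith


def saturation_vapor_pressure(temp_c: float) -> float:
    """Saturation vapour pressure e0(T) (kPa), Tetens form."""
    return 0.6108 * math.exp(17.27 * temp_c / (temp_c + 237.3))


def pm_daily_inputs(
    weather: DailyWeatherRecord, site: SiteMetadata
) -> PMDailyInputs:
    """Assemble the FAO-56 daily auxiliary terms for one record.

    Saturation vapour pressure is the mean of e0 at Tmax and Tmin; actual
    vapour pressure comes from mean relative humidity; the vapour-pressure
    slope is evaluated at Tmean; the psychrometric constant follows from
    barometric pressure at the site elevation; net radiation balances
    shortwave (albedo 0.23) against clear-sky-scaled longwave; soil heat
    flux is zero at the daily step.
    """
    if weather.rh_mean is None:
        raise ValueError(f"{weather.date}: relative humidity required for P-M")
    if weather.wind_2m is None:
        raise ValueError(f"{weather.date}: 2-m wind speed required for P-M")
    if weather.solar_rad is None:
        raise ValueError(
            f"{weather.date}: solar radiation absent; fill from sunshine first"
        )
    tmean = weather.tmean
    es = 0.5 * (
        saturation_vapor_pressure(weather.tmax)
        + saturation_vapor_pressure(weather.tmin)
    )
    ea = min(es, weather.rh_mean / 100.0 * es)
    slope = (
        4098.0 * saturation_vapor_pressure(tmean) / (tmean + 237.3) ** 2
    )
    pressure = 101.3 * ((293.0 - 0.0065 * site.elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure

    doy = day_of_year(weather.date)
    diy = days_in_year(weather.date.year)
    ra = extraterrestrial_radiation(site.latitude_rad, doy, diy)
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rs = weather.solar_rad
    rns = (1.0 - 0.23) * rs
    rel = min(1.0, rs / rso) if rso > 0 else 1.0
    tmax_k4 = (weather.tmax + 273.16) ** 4
    tmin_k4 = (weather.tmin + 273.16) ** 4
    rnl = (
        _SIGMA
        * 0.5
        * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * rel - 0.35)
    )
    return PMDailyInputs(
        net_radiation=rns - rnl,
        soil_heat_flux=0.0,
        tmean=tmean,
        u2=weather.wind_2m,
        es=es,
        ea=ea,
        slope=slope,
        gamma=gamma,
    )


def et0_penman_monteith_from_inputs(inp: PMDailyInputs) -> float:
    """Evaluate the Penman-Monteith equation on assembled daily terms.

    ET0 = [0.408 Delta (Rn - G) + gamma 900/(Tmean+273) u2 (es - ea)]
          / [Delta + gamma (1 + 0.34 u2)], floored at zero.
    """
    num = 0.408 * inp.slope * (inp.net_radiation - inp.soil_heat_flux) + (
        inp.gamma * 900.0 / (inp.tmean + 273.0) * inp.u2 * (inp.es - inp.ea)
    )
    den = inp.slope + inp.gamma * (1.0 + 0.34 * inp.u2)
    et0 = num / den
    if et0 < 0:
        logger.debug("negative P-M ET0 %.3f floored to 0", et0)
    return max(0.0, et0)


def et0_penman_monteith(
    weather: DailyWeatherRecord, site: SiteMetadata
) -> float:
    """Daily FAO-56 Penman-Monteith ET0 (mm d-1)."""
    return et0_penman_monteith_from_inputs(pm_daily_inputs(weather, site))


# ---------------------------------------------------------------------------
# Hargreaves


def et0_hargreaves(
    tmax: float,
    tmin: float,
    ra: float,
    params: HargreavesParams = HargreavesParams(),
    strict_printed_sum: bool = False,
) -> float:
    """Daily Hargreaves ET0 (mm d-1).

    ET0 = (K / lambda) * (Tmax - Tmin)^n * ((Tmax + Tmin)/2 + Toff) * Ra,
    floored at zero. ``strict_printed_sum=True`` switches the first factor
    to (Tmax + Tmin)^n for auditing against sources that print the sum; the
    difference form is the standard Hargreaves-Samani model and the default.
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    if ra < 0:
        raise ValueError("Ra must be nonnegative")
    base = (tmax + tmin) if strict_printed_sum else (tmax - tmin)
    if base < 0:
        return 0.0
    et0 = (
        params.K
        / params.lambda_
        * base**params.n_exp
        * (0.5 * (tmax + tmin) + params.T_off)
        * ra
    )
    return max(0.0, et0)
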