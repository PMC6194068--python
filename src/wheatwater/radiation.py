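"""Astronomical and empirical solar-radiation terms.

Daily extraterrestrial radiation and its astronomical ingredients (inverse
relative earth-sun distance, solar declination, sunset hour angle), maximum
possible sunshine duration, and the Angstrom-Prescott estimate of surface
shortwave radiation from sunshine duration with season-specific regression
coefficients for the Huang-Huai-Hai Plain.

All angles are radians; day-of-year is 1-based (Jan 1 = 1); radiation is
MJ m-2 d-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "Season",
    "AngstromCoefficients",
    "ANGSTROM_DEFAULTS",
    "season_for_month",
    "inverse_relative_distance",
    "solar_declination",
    "sunset_hour_angle",
    "extraterrestrial_radiation",
    "daylength",
    "angstrom_solar_radiation",
]

#: Solar constant bundle of the daily extraterrestrial-radiation formula,
#: 24*60*0.0820 MJ m-2 d-1 expressed as 118.08.
_RA_CONSTANT = 118.08

#: Amplitude of the solar-declination seasonal cycle, rad (23.45 deg).
_DECLINATION_AMPLITUDE = 0.409


class Season(str, Enum):
    SPRING = "spring"
    SUMMER = "summer"
    AUTUMN = "autumn"
    WINTER = "winter"


@dataclass(frozen=True)
class AngstromCoefficients:
    """Angstrom-Prescott regression constants for one season.

    ``a_s`` is the fraction of extraterrestrial radiation reaching the
    surface on a fully overcast day; ``a_s + b_s`` the fraction on a clear
    day, so physically ``a_s + b_s <= 1``.
    """

    a_s: float
    b_s: float
    season: Season

    def __post_init__(self) -> None:
        if not (self.a_s > 0 and self.b_s > 0):
            raise ValueError("Angstrom coefficients must be positive")
        if self.a_s + self.b_s > 1.0 + 1e-12:
            raise ValueError("a_s + b_s must not exceed 1")


# Seasonal regression constants calibrated for the Huang-Huai-Hai Plain.
ANGSTROM_DEFAULTS: dict[Season, AngstromCoefficients] = {
    Season.SPRING: AngstromCoefficients(0.152, 0.556, Season.SPRING),
    Season.SUMMER: AngstromCoefficients(0.115, 0.588, Season.SUMMER),
    Season.AUTUMN: AngstromCoefficients(0.301, 0.311, Season.AUTUMN),
    Season.WINTER: AngstromCoefficients(0.172, 0.536, Season.WINTER),
}

_MONTH_SEASON = {
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.AUTUMN, 10: Season.AUTUMN, 11: Season.AUTUMN,
}


def season_for_month(month: int) -> Season:
    """Meteorological season: Mar-May spring, Jun-Aug summer, Sep-Nov autumn,
    Dec-Feb winter."""
    if month not in _MONTH_SEASON:
        raise ValueError(f"month must be 1..12, got {month}")
    return _MONTH_SEASON[month]


def _check_doy(day_of_year: int, days_in_year: int) -> None:
    if days_in_year not in (365, 366):
        raise ValueError(f"days_in_year must be 365 or 366, got {days_in_year}")
    if not 1 <= day_of_year <= days_in_year:
        raise ValueError(
            f"day_of_year must be in 1..{days_in_year}, got {day_of_year}"
        )


def inverse_relative_distance(day_of_year: int, days_in_year: int = 365) -> float:
    """Inverse relative earth-sun distance d_r (dimensionless).

    d_r = 1 + 0.033 cos(2*pi*J/D); bounded by [0.967, 1.033].
    """
    _check_doy(day_of_year, days_in_year)
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / days_in_year)


def solar_declination(day_of_year: int, days_in_year: int = 365) -> float:
    """Solar declination delta (rad): 0.409 sin(2*pi*J/D - 1.39)."""
    _check_doy(day_of_year, days_in_year)
    return _DECLINATION_AMPLITUDE * math.sin(
        2.0 * math.pi * day_of_year / days_in_year - 1.39
    )


def sunset_hour_angle(latitude: float, declination: float) -> float:
    """Sunset hour angle omega_s (rad) = arccos(-tan(phi) tan(delta)).

    The arccos argument is clipped to [-1, 1] so the function is total:
    polar day yields pi, polar night yields 0.
    """
    if abs(latitude) > math.pi / 2:
        raise ValueError(f"latitude must be within +-pi/2 rad, got {latitude}")
    x = -math.tan(latitude) * math.tan(declination)
    return math.acos(min(1.0, max(-1.0, x)))


def extraterrestrial_radiation(
    latitude: float, day_of_year: int, days_in_year: int = 365
) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1) at a given latitude.

    Ra = (118.08/pi) d_r [omega_s sin(phi) sin(delta)
                          + cos(phi) cos(delta) sin(omega_s)]

    Parameters
    ----------
    latitude : float
        Geographic latitude, radians, positive north.
    day_of_year : int
        1-based day of the calendar year.
    days_in_year : int
        365 or 366, from the calendar year of the record.
    """
    dr = inverse_relative_distance(day_of_year, days_in_year)
    delta = solar_declination(day_of_year, days_in_year)
    ws = sunset_hour_angle(latitude, delta)
    bracket = ws * math.sin(latitude) * math.sin(delta) + math.cos(
        latitude
    ) * math.cos(delta) * math.sin(ws)
    return max(0.0, _RA_CONSTANT / math.pi * dr * bracket)


def daylength(sunset_hour_angle_rad: float) -> float:
    """Maximum possible sunshine duration N (h) = 24 omega_s / pi."""
    if not 0.0 <= sunset_hour_angle_rad <= math.pi + 1e-12:
        raise ValueError(
            f"sunset hour angle must be in [0, pi], got {sunset_hour_angle_rad}"
        )
    return 24.0 * sunset_hour_angle_rad / math.pi


def angstrom_solar_radiation(
    sunshine_hours: float,
    max_sunshine_hours: float,
    extraterrestrial: float,
    month: int,
    coefficients: dict[Season, AngstromCoefficients] | None = None,
) -> float:
    """Surface shortwave radiation Rs (MJ m-2 d-1) from sunshine duration.

    Rs = (a_s + b_s * n/N) * Ra with season-specific (a_s, b_s) selected by
    calendar month. Sunshine exceeding the astronomical daylength is clipped
    to N with a warning (sub-daily logging artefacts); when N = 0 (polar
    night) the overcast fraction a_s applies.
    """
    if sunshine_hours < 0 or max_sunshine_hours < 0 or extraterrestrial < 0:
        raise ValueError("sunshine, daylength and Ra must be nonnegative")
    coeff = (coefficients or ANGSTROM_DEFAULTS)[season_for_month(month)]
    if sunshine_hours > max_sunshine_hours:
        warnings.warn(
            f"sunshine {sunshine_hours:.2f} h exceeds daylength "
            f"{max_sunshine_hours:.2f} h; clipping",
            stacklevel=2,
        )
        sunshine_hours = max_sunshine_hours
    frac = sunshine_hours / max_sunshine_hours if max_sunshine_hours > 0 else 0.0
    return (coeff.a_s + coeff.b_s * frac) * extraterrestrial
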