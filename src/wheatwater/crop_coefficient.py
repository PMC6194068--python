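"""Crop-coefficient (Kc) models driven by leaf area index, and a parametric
LAI-trajectory generator.

Two Kc formulations are provided. The linear EORATIO form used by DSSAT's
Penman-Monteith pathway,

    Kc = 1.0 + (EORATIO - 1.0) * LAI / 6.0   (LAI capped at 6.0),

keeps Kc >= 1 all season, which overstates transpiration from a sparse
early-season canopy. The dynamic exponential form,

    Kc = Kc_min + (Kc_max - Kc_min) * (1 - exp(-0.5 LAI)),

starts at Kc_min over bare soil and saturates towards Kc_max as the canopy
closes (winter-wheat defaults 0.4 and 1.15). Daily crop evapotranspiration
is ETc = Kc * ET0.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "KcOriginalParams",
    "KcDynamicParams",
    "LAICurveParams",
    "kc_original",
    "kc_dynamic",
    "generate_lai_series",
    "etc_daily",
]

#: LAI ceiling of the linear EORATIO form.
_LAI_CAP = 6.0

#: Canopy-extinction rate of the exponential Kc form, per unit LAI.
_KC_DECAY = 0.5


@dataclass(frozen=True)
class KcOriginalParams:
    eoratio: float = 1.1

    def __post_init__(self) -> None:
        if self.eoratio < 1.0:
            raise ValueError("eoratio must be >= 1.0")


@dataclass(frozen=True)
class KcDynamicParams:
    kc_min: float = 0.4
    kc_max: float = 1.15

    def __post_init__(self) -> None:
        if not 0.0 < self.kc_min < self.kc_max:
            raise ValueError("need 0 < kc_min < kc_max")


@dataclass(frozen=True)
class LAICurveParams:
    """Parameters of the synthetic rise-and-senesce LAI trajectory.

    Day offsets count from the start of the season series. The curve is 0
    before ``emergence_day``, rises with a saturating exponential to exactly
    ``max_lai`` at ``peak_day``, then decays exponentially at
    ``senescence_rate``.
    """

    emergence_day: int = 15
    peak_day: int = 170
    max_lai: float = 7.9
    rise_rate: float = 0.035
    senescence_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.emergence_day >= self.peak_day:
            raise ValueError("emergence_day must precede peak_day")
        if self.max_lai <= 0:
            raise ValueError("max_lai must be positive")
        if self.rise_rate <= 0 or self.senescence_rate <= 0:
            raise ValueError("rates must be positive")


def kc_original(lai: float, params: KcOriginalParams = KcOriginalParams()) -> float:
    """Linear EORATIO crop coefficient; LAI above 6.0 is capped."""
    if lai < 0:
        raise ValueError("lai must be nonnegative")
    return 1.0 + (params.eoratio - 1.0) * min(lai, _LAI_CAP) / _LAI_CAP


def kc_dynamic(lai: float, params: KcDynamicParams = KcDynamicParams()) -> float:
    """Exponential-saturation crop coefficient; strictly increasing in LAI,
    equal to kc_min at LAI = 0 and approaching kc_max from below."""
    if lai < 0:
        raise ValueError("lai must be nonnegative")
    return params.kc_min + (params.kc_max - params.kc_min) * (
        1.0 - math.exp(-_KC_DECAY * lai)
    )


def generate_lai_series(
    params: LAICurveParams, season_dates: Sequence[dt.date]
) -> list[tuple[dt.date, float]]:
    """Deterministic unimodal LAI trajectory over a date-sorted season.

    Rise phase: lai(t) = max_lai * (1 - e^{-r (t-t_e)}) / (1 - e^{-r (t_p-t_e)})
    so the peak value is exactly ``max_lai`` at ``peak_day``; afterwards
    lai(t) = max_lai * e^{-s (t - t_p)}.
    """
    dates = list(season_dates)
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("season dates must be strictly increasing")
    rise_span = params.peak_day - params.emergence_day
    rise_norm = 1.0 - math.exp(-params.rise_rate * rise_span)
    out = []
    for k, date in enumerate(dates):
        if k < params.emergence_day:
            lai = 0.0
        elif k <= params.peak_day:
            lai = (
                params.max_lai
                * (1.0 - math.exp(-params.rise_rate * (k - params.emergence_day)))
                / rise_norm
            )
        else:
            lai = params.max_lai * math.exp(
                -params.senescence_rate * (k - params.peak_day)
            )
        out.append((date, lai))
    return out


def etc_daily(et0: float, kc: float) -> float:
    """Daily crop evapotranspiration ETc = Kc * ET0 (mm d-1)."""
    if et0 < 0:
        raise ValueError("et0 must be nonnegative")
    if kc <= 0:
        raise ValueError("kc must be positive")
    return kc * et0
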