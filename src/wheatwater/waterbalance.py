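"""Seasonal water accounting: observed ETc from a field water balance,
growth-stage aggregation, effective precipitation, and the irrigation
water requirement.

Observed crop evapotranspiration over a period closes the soil water
balance

    ETc = (M1 + P + I + CR) - (M2 + D + R)

with initial/final profile moisture M1/M2, precipitation P, irrigation I,
capillary rise CR (zero where the water table is deep), deep drainage D and
runoff R, all in mm. The seasonal irrigation water requirement is the part
of ETc not met by effective precipitation: IWR = ETc - Peff.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "WaterBalanceComponents",
    "StageDefinition",
    "SeasonalSummary",
    "observed_etc",
    "aggregate_stages",
    "effective_precipitation",
    "irrigation_water_requirement",
]


@dataclass(frozen=True)
class WaterBalanceComponents:
    """The seven balance terms, mm, all nonnegative."""

    m1_initial_soil_moisture: float
    m2_final_soil_moisture: float
    precipitation: float
    irrigation: float
    capillary_rise: float = 0.0
    deep_drainage: float = 0.0
    runoff: float = 0.0

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if val < 0:
                raise ValueError(f"{name} must be nonnegative, got {val}")


@dataclass(frozen=True)
class StageDefinition:
    """A phenological stage window, inclusive of both endpoint dates."""

    label: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(f"stage {self.label!r}: start after end")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class SeasonalSummary:
    """Season totals (mm): ETc, effective precipitation, and their
    difference, the irrigation water requirement."""

    etc_total: float
    effective_precip: float
    iwr: float


def observed_etc(components: WaterBalanceComponents) -> float:
    """Observed ETc (mm) closing the water balance; may be negative under
    measurement error (flagged by the caller, never clamped here)."""
    c = components
    return (
        c.m1_initial_soil_moisture
        + c.precipitation
        + c.irrigation
        + c.capillary_rise
    ) - (c.m2_final_soil_moisture + c.deep_drainage + c.runoff)


def aggregate_stages(
    daily_etc: Mapping[dt.date, float] | pd.Series,
    stages: Sequence[StageDefinition],
) -> dict[str, float]:
    """Sum a dated daily series over stage windows (endpoints inclusive).

    Every stage must lie within the series' date span; stage windows may
    deliberately exclude days (e.g. unmeasured inter-stage gaps), and a
    whole-season stage may overlap the others.
    """
    series = pd.Series(dict(daily_etc)).sort_index()
    if series.empty:
        raise ValueError("daily series is empty")
    span_lo, span_hi = series.index.min(), series.index.max()
    out: dict[str, float] = {}
    for stage in stages:
        if stage.start_date < span_lo or stage.end_date > span_hi:
            raise ValueError(
                f"stage {stage.label!r} ({stage.start_date}..{stage.end_date}) "
                f"outside data span {span_lo}..{span_hi}"
            )
        mask = (series.index >= stage.start_date) & (series.index <= stage.end_date)
        out[stage.label] = float(series[mask].sum())
    return out


def _usda_scs_monthly(p_month: float) -> float:
    # USDA-SCS monthly effective precipitation (FAO irrigation scheduling form)
    if p_month <= 250.0:
        return p_month * (125.0 - 0.2 * p_month) / 125.0
    return 125.0 + 0.1 * p_month


def effective_precipitation(
    daily_precip: Mapping[dt.date, float] | pd.Series,
    method: str = "usda_scs",
    fraction: float = 0.8,
) -> float:
    """Effective precipitation (mm) over the series' period.

    ``usda_scs`` applies the USDA Soil Conservation Service monthly formula
    Pe = P (125 - 0.2 P)/125 for monthly totals up to 250 mm, else
    125 + 0.1 P, and sums over calendar months. ``fixed_fraction``
    multiplies total precipitation by ``fraction``. Both are bounded by the
    total precipitation.
    """
    series = pd.Series(dict(daily_precip)).sort_index()
    if (series < 0).any():
        raise ValueError("precipitation must be nonnegative")
    if method == "fixed_fraction":
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        return float(series.sum() * fraction)
    if method == "usda_scs":
        idx = pd.DatetimeIndex(series.index)
        monthly = series.groupby([idx.year, idx.month]).sum()
        return float(sum(_usda_scs_monthly(p) for p in monthly))
    raise ValueError(f"unknown effective-precipitation method {method!r}")


def irrigation_water_requirement(
    etc_total: float, effective_precip: float, floor_at_zero: bool = False
) -> float:
    """Irrigation water requirement IWR = ETc - Peff (mm).

    Left unclamped by default so the seasonal identity IWR + Peff = ETc
    holds exactly; ``floor_at_zero`` is for daily-scale deficit accounting
    where surplus days contribute no requirement.
    """
    if etc_total < 0 or effective_precip < 0:
        raise ValueError("inputs must be nonnegative")
    iwr = etc_total - effective_precip
    return max(0.0, iwr) if floor_at_zero else iwr
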