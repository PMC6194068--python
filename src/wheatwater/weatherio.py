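"""Weather and site records, delimited-text io, and a seeded synthetic
weather generator.

Two on-disk dialects are supported:

``csv``
    Comma-separated with a header row and ISO-8601 dates. Columns:
    ``date,tmax,tmin,rh_mean,wind_2m,sunshine_hours,precip,solar_rad``.
    Optional fields are left blank when absent.

``dssat_wth``
    A minimal DSSAT-style weather file: a station header line, an
    ``@ INSI LAT LONG ELEV`` site line, then fixed columns
    ``@DATE SRAD TMAX TMIN RAIN RHUM WIND SUNH`` with YYDDD dates and
    ``-99`` sentinels for missing values.

Missing optional values are represented as ``None`` — never silently zero;
solar radiation left absent here is filled downstream from sunshine duration
via the Angstrom relation.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from wheatwater.radiation import daylength, solar_declination, sunset_hour_angle

__all__ = [
    "DailyWeatherRecord",
    "SiteMetadata",
    "ClimateParams",
    "read_weather_table",
    "write_weather_table",
    "generate_synthetic_weather",
    "records_to_frame",
    "day_of_year",
    "days_in_year",
]

_CSV_COLUMNS = [
    "date",
    "tmax",
    "tmin",
    "rh_mean",
    "wind_2m",
    "sunshine_hours",
    "precip",
    "solar_rad",
]

_MISSING = -99.0


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One station-day of meteorology.

    Temperatures in deg C, humidity in percent, wind at 2 m in m s-1,
    sunshine in hours, precipitation in mm, solar radiation in MJ m-2 d-1.
    Optional fields are ``None`` when unobserved.
    """

    date: dt.date
    tmax: float
    tmin: float
    rh_mean: float | None = None
    wind_2m: float | None = None
    sunshine_hours: float | None = None
    precip: float = 0.0
    solar_rad: float | None = None

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise ValueError(
                f"{self.date}: tmax ({self.tmax}) < tmin ({self.tmin})"
            )
        if self.rh_mean is not None and not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"{self.date}: rh_mean must be in [0, 100]")
        if self.wind_2m is not None and self.wind_2m < 0:
            raise ValueError(f"{self.date}: wind_2m must be nonnegative")
        if self.sunshine_hours is not None and not 0.0 <= self.sunshine_hours <= 24.0:
            raise ValueError(f"{self.date}: sunshine_hours must be in [0, 24]")
        if self.precip < 0:
            raise ValueError(f"{self.date}: precip must be nonnegative")
        if self.solar_rad is not None and self.solar_rad < 0:
            raise ValueError(f"{self.date}: solar_rad must be nonnegative")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class SiteMetadata:
    """Station identity and geography (latitude in decimal degrees,
    positive north; elevation in m above sea level)."""

    station_id: str
    latitude: float
    longitude: float = float("nan")
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude must be in [-90, 90], got {self.latitude}")

    @property
    def latitude_rad(self) -> float:
        return math.radians(self.latitude)


def day_of_year(date: dt.date) -> int:
    """1-based day of year (Jan 1 = 1)."""
    return date.timetuple().tm_yday


def days_in_year(year: int) -> int:
    return 366 if dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365


def records_to_frame(records: Sequence[DailyWeatherRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with one row per day (NaN for absent
    optional fields)."""
    return pd.DataFrame(
        {
            "date": [r.date for r in records],
            "tmax": [r.tmax for r in records],
            "tmin": [r.tmin for r in records],
            "rh_mean": [r.rh_mean for r in records],
            "wind_2m": [r.wind_2m for r in records],
            "sunshine_hours": [r.sunshine_hours for r in records],
            "precip": [r.precip for r in records],
            "solar_rad": [r.solar_rad for r in records],
        }
    )


# ---------------------------------------------------------------------------
# readers / writers


def _opt(value: float | None) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def read_weather_table(path, dialect: str = "csv") -> list[DailyWeatherRecord]:
    """Read a daily weather table.

    Records are returned sorted by date; duplicate dates are a hard error
    and calendar gaps are reported in the (harmless) ``gaps`` attribute of
    the returned list's frame — gaps are allowed but never filled here.
    """
    if dialect == "csv":
        records = _read_csv(path)
    elif dialect == "dssat_wth":
        records = _read_wth(path)
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")
    records.sort(key=lambda r: r.date)
    seen: set[dt.date] = set()
    for r in records:
        if r.date in seen:
            raise ValueError(f"duplicate date {r.date} in {path}")
        seen.add(r.date)
    return records


def _read_csv(path) -> list[DailyWeatherRecord]:
    df = pd.read_csv(path)
    missing = {"date", "tmax", "tmin"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            date = dt.date.fromisoformat(str(row["date"]))
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: unparseable date "
                             f"{row['date']!r}") from exc
        try:
            records.append(
                DailyWeatherRecord(
                    date=date,
                    tmax=float(row["tmax"]),
                    tmin=float(row["tmin"]),
                    rh_mean=_opt(row.get("rh_mean")),
                    wind_2m=_opt(row.get("wind_2m")),
                    sunshine_hours=_opt(row.get("sunshine_hours")),
                    precip=float(row.get("precip", 0.0) or 0.0),
                    solar_rad=_opt(row.get("solar_rad")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return records


def _yyddd(date: dt.date) -> str:
    return f"{date.year % 100:02d}{day_of_year(date):03d}"


def _parse_yyddd(token: str, line_no: int, path) -> dt.date:
    if len(token) != 5 or not token.isdigit():
        raise ValueError(f"{path} line {line_no}: bad DSSAT date {token!r}")
    yy, ddd = int(token[:2]), int(token[2:])
    year = 2000 + yy if yy < 50 else 1900 + yy
    try:
        return dt.date(year, 1, 1) + dt.timedelta(days=ddd - 1)
    except (ValueError, OverflowError) as exc:
        raise ValueError(f"{path} line {line_no}: bad DSSAT date {token!r}") from exc


def _read_wth(path) -> list[DailyWeatherRecord]:
    records = []
    with open(path) as fh:
        lines = fh.readlines()
    in_data = False
    for line_no, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("*") or stripped.startswith("!"):
            continue
        if stripped.startswith("@"):
            in_data = stripped.upper().startswith("@DATE")
            continue
        if not in_data:
            continue
        tokens = stripped.split()
        if len(tokens) < 4:
            raise ValueError(f"{path} line {line_no}: expected at least "
                             "DATE SRAD TMAX TMIN")
        date = _parse_yyddd(tokens[0], line_no, path)
        vals = [float(t) for t in tokens[1:]] + [_MISSING] * 7
        srad, tmax, tmin, rain, rhum, wind, sunh = vals[:7]

        def v(x: float) -> float | None:
            return None if x == _MISSING else x

        try:
            records.append(
                DailyWeatherRecord(
                    date=date,
                    tmax=tmax,
                    tmin=tmin,
                    rh_mean=v(rhum),
                    wind_2m=v(wind),
                    sunshine_hours=v(sunh),
                    precip=0.0 if rain == _MISSING else rain,
                    solar_rad=v(srad),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return records


def write_weather_table(
    records: Sequence[DailyWeatherRecord],
    path,
    dialect: str = "csv",
    site: SiteMetadata | None = None,
) -> None:
    """Write records so that :func:`read_weather_table` recovers them.

    Values are written at 0.1 precision for temperatures, precipitation and
    sunshine, 0.01 for wind and radiation. Records must be date-sorted and
    duplicate-free.
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty weather table")
    dates = [r.date for r in records]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("records must be strictly date-sorted (no duplicates)")
    if dialect == "csv":
        _write_csv(records, path)
    elif dialect == "dssat_wth":
        _write_wth(records, path, site)
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")


def _fmt(value: float | None, decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def _write_csv(records: Sequence[DailyWeatherRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                ",".join(
                    [
                        r.date.isoformat(),
                        f"{r.tmax:.1f}",
                        f"{r.tmin:.1f}",
                        _fmt(r.rh_mean, 1),
                        _fmt(r.wind_2m, 2),
                        _fmt(r.sunshine_hours, 1),
                        f"{r.precip:.1f}",
                        _fmt(r.solar_rad, 2),
                    ]
                )
                + "\n"
            )


def _wth_num(value: float | None, width: int, decimals: int) -> str:
    x = _MISSING if value is None else value
    return f"{x:{width}.{decimals}f}"


def _write_wth(
    records: Sequence[DailyWeatherRecord], path, site: SiteMetadata | None
) -> None:
    site = site or SiteMetadata("XXXX", 0.0, 0.0, 0.0)
    lon = 0.0 if math.isnan(site.longitude) else site.longitude
    with open(path, "w") as fh:
        fh.write(f"*WEATHER DATA : {site.station_id}\n\n")
        fh.write("@ INSI      LAT     LONG  ELEV\n")
        fh.write(
            f"  {site.station_id[:4].upper():<4} {site.latitude:8.3f} "
            f"{lon:8.3f} {site.elevation:5.0f}\n"
        )
        fh.write("@DATE  SRAD  TMAX  TMIN  RAIN  RHUM  WIND  SUNH\n")
        for r in records:
            fields = [
                _yyddd(r.date),
                _wth_num(r.solar_rad, 6, 2),
                _wth_num(r.tmax, 5, 1),
                _wth_num(r.tmin, 5, 1),
                _wth_num(r.precip, 5, 1),
                _wth_num(r.rh_mean, 5, 1),
                _wth_num(r.wind_2m, 5, 2),
                _wth_num(r.sunshine_hours, 5, 1),
            ]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# synthetic weather


@dataclass(frozen=True)
class ClimateParams:
    """Climate normals driving the synthetic generator.

    Defaults describe a temperate continental plain site (northern Henan):
    mean annual temperature 14.1 deg C, annual rainfall near 580 mm realized
    as intermittent wet days (probability 0.25, mean depth 6.4 mm), mean
    diurnal range 10 deg C and a sunshine fraction of 0.55.
    """

    annual_mean_temp: float = 14.1
    annual_temp_amplitude: float = 14.0
    diurnal_range: float = 10.0
    wet_day_prob: float = 0.25
    mean_wet_depth: float = 6.4
    mean_sunshine_fraction: float = 0.55

    def __post_init__(self) -> None:
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise ValueError("wet_day_prob must be in [0, 1]")
        if not 0.0 <= self.mean_sunshine_fraction <= 1.0:
            raise ValueError("mean_sunshine_fraction must be in [0, 1]")
        if self.mean_wet_depth < 0:
            raise ValueError("mean_wet_depth must be nonnegative")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be nonnegative")
        if self.annual_temp_amplitude < 0:
            raise ValueError("annual_temp_amplitude must be nonnegative")


def generate_synthetic_weather(
    site: SiteMetadata,
    start_date: dt.date,
    n_days: int,
    seed: int,
    climate: ClimateParams | None = None,
) -> list[DailyWeatherRecord]:
    """Generate a deterministic synthetic daily weather series.

    The temperature climatology is sinusoidal over the year (warmest near
    day 200 in the northern hemisphere, mirrored in the south) with AR(1)
    day-to-day anomalies; precipitation is a two-state occurrence process
    with gamma-distributed wet-day depths, both modulated seasonally so rain
    concentrates in the warm months (monsoon-type regime) while the
    annual-mean occurrence stays at ``wet_day_prob``; sunshine hours follow the
    astronomical daylength scaled by a beta-perturbed sunshine fraction that
    drops on wet days; humidity rises and temperature range narrows on wet
    days. Values are rounded to the io precision (0.1 / 0.01) so a written
    file round-trips exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    climate = climate or ClimateParams()
    rng = np.random.default_rng(seed)
    phi_rad = site.latitude_rad
    warm_peak_doy = 201.0 if site.latitude >= 0 else 201.0 - 182.5

    records: list[DailyWeatherRecord] = []
    anomaly = 0.0
    for k in range(n_days):
        date = start_date + dt.timedelta(days=k)
        doy = day_of_year(date)
        diy = days_in_year(date.year)
        # seasonal mean with AR(1) anomaly (sd ~2 degC, lag-1 corr 0.7)
        seasonal = climate.annual_mean_temp + climate.annual_temp_amplitude * math.cos(
            2.0 * math.pi * (doy - warm_peak_doy) / diy
        )
        anomaly = 0.7 * anomaly + rng.normal(0.0, 2.0) * math.sqrt(1 - 0.7**2)
        # monsoon-type concentration: wet-day odds and depths peak with the
        # warm season; the annual-mean occurrence equals wet_day_prob
        seas = math.cos(2.0 * math.pi * (doy - warm_peak_doy) / diy)
        p_wet = min(1.0, max(0.0, climate.wet_day_prob * (1.0 + 0.85 * seas)))
        wet = rng.random() < p_wet
        precip = 0.0
        if wet and climate.mean_wet_depth > 0:
            # 1.2125 = 1 + 0.85*0.5*E[cos^2]: cancels the occurrence-depth
            # covariance so the annual total stays p * depth * 365
            depth = climate.mean_wet_depth * (1.0 + 0.5 * seas) / 1.2125
            precip = rng.gamma(shape=0.8, scale=depth / 0.8)
        # diurnal range shrinks under cloud; keep strictly nonnegative
        drange = max(
            0.0,
            rng.normal(
                climate.diurnal_range * (0.7 if wet else 1.0),
                0.15 * climate.diurnal_range,
            ),
        )
        tmean = seasonal + anomaly
        tmax = tmean + 0.5 * drange
        tmin = tmean - 0.5 * drange

        ws = sunset_hour_angle(phi_rad, solar_declination(doy, diy))
        n_max = daylength(ws)
        frac = climate.mean_sunshine_fraction * (0.3 if wet else 1.0)
        frac = min(1.0, max(0.0, frac + rng.normal(0.0, 0.1)))
        sunshine = frac * n_max

        rh = min(100.0, max(0.0, rng.normal(85.0 if wet else 62.0, 8.0)))
        wind = rng.lognormal(mean=math.log(2.0), sigma=0.4)

        records.append(
            DailyWeatherRecord(
                date=date,
                tmax=round(tmax, 1),
                tmin=round(min(tmin, tmax), 1),
                rh_mean=round(rh, 1),
                wind_2m=round(wind, 2),
                sunshine_hours=round(sunshine, 1),
                precip=round(precip, 1),
                solar_rad=None,
            )
        )
    return records


def fill_solar_from_sunshine(
    records: Sequence[DailyWeatherRecord], site: SiteMetadata
) -> list[DailyWeatherRecord]:
    """Fill absent solar radiation via the Angstrom relation; records with
    observed radiation are left untouched. Records lacking both radiation
    and sunshine raise."""
    from wheatwater.radiation import (
        angstrom_solar_radiation,
        extraterrestrial_radiation,
    )

    out = []
    for r in records:
        if r.solar_rad is not None:
            out.append(r)
            continue
        if r.sunshine_hours is None:
            raise ValueError(
                f"{r.date}: neither solar radiation nor sunshine hours present"
            )
        doy = day_of_year(r.date)
        diy = days_in_year(r.date.year)
        ra = extraterrestrial_radiation(site.latitude_rad, doy, diy)
        ws = sunset_hour_angle(site.latitude_rad, solar_declination(doy, diy))
        rs = angstrom_solar_radiation(
            r.sunshine_hours, daylength(ws), ra, r.date.month
        )
        out.append(replace(r, solar_rad=rs))
    return out
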