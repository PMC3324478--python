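"""Daily station weather series and derived meteorological variables.

The central container is :class:`StationSeries`: a gap-free daily record of
mean temperature, minimum temperature, precipitation and (optionally)
relative humidity for one station, together with the station coordinates
needed for photoperiod. Derived quantities used by the phenology models —
vapour pressure deficit, astronomical day length, previous-year annual
precipitation — live here as plain functions.

Conventions: day-of-year (DOY) is the 1-based Julian day within the
calendar year; leap years follow the real calendar (DOY up to 366). All
date windows are inclusive of both endpoints.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import CoverageError, DataValidationError, DomainError

__all__ = [
    "DailyRecord",
    "StationSeries",
    "LeafingObservation",
    "saturation_vapor_pressure",
    "compute_vpd",
    "compute_photoperiod",
    "annual_precip",
    "slice_window",
    "days_in_year",
]

WEATHER_COLUMNS = ("tmean", "tmin", "precip", "rh")


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def saturation_vapor_pressure(tmean):
    """Tetens saturation vapour pressure over water, in Pa.

    es(T) = 610.7 * 10**(7.5 T / (237.3 + T)) with T in deg C.
    """
    t = np.asarray(tmean, dtype=float)
    es = 610.7 * 10.0 ** (7.5 * t / (237.3 + t))
    return float(es) if np.isscalar(tmean) else es


def compute_vpd(tmean, rh):
    """Vapour pressure deficit in Pa from mean temperature and humidity.

    VPD = es(tmean) * (1 - rh/100). Saturated air (rh=100) gives 0.
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise DomainError(f"relative humidity outside [0, 100]: {rh!r}")
    vpd = saturation_vapor_pressure(tmean) * (1.0 - rh_arr / 100.0)
    return float(vpd) if np.isscalar(rh) and np.isscalar(tmean) else vpd


def compute_photoperiod(latitude: float, doy):
    """Astronomical day length in seconds from the sunrise equation.

    Solar declination delta(doy) = 0.409 sin(2 pi doy / 365 - 1.39) rad,
    hour angle omega = arccos(-tan(phi) tan(delta)); day length is
    (omega / pi) * 86400 s. No atmospheric refraction. Polar latitudes
    (|phi| >= 66.5) are outside the supported domain.
    """
    if abs(latitude) >= 66.5:
        raise DomainError(f"latitude {latitude} in polar zone; day length undefined here")
    d = np.asarray(doy, dtype=float)
    decl = 0.409 * np.sin(2.0 * np.pi * d / 365.0 - 1.39)
    cos_omega = -np.tan(np.radians(latitude)) * np.tan(decl)
    omega = np.arccos(np.clip(cos_omega, -1.0, 1.0))
    seconds = omega / np.pi * 86400.0
    return float(seconds) if np.isscalar(doy) else seconds


@dataclass(frozen=True)
class DailyRecord:
    """One day of station weather. ``rh`` is None when not observed."""

    date: dt.date
    tmean: float
    tmin: float
    precip: float
    rh: float | None = None

    def __post_init__(self):
        if self.precip < 0:
            raise DataValidationError(f"{self.date}: negative precipitation {self.precip}")
        if self.tmin > self.tmean:
            raise DataValidationError(
                f"{self.date}: tmin {self.tmin} exceeds tmean {self.tmean}"
            )
        if self.rh is not None and not (0.0 <= self.rh <= 100.0):
            raise DataValidationError(f"{self.date}: rh {self.rh} outside [0, 100]")


@dataclass(frozen=True)
class LeafingObservation:
    """Observed first-leaf date for one station/species/year, as DOY."""

    station_id: str
    species: str
    year: int
    leafing_doy: int

    def __post_init__(self):
        if not 1 <= self.leafing_doy <= days_in_year(self.year):
            raise DataValidationError(
                f"leafing DOY {self.leafing_doy} outside [1, {days_in_year(self.year)}] "
                f"for year {self.year}"
            )


@dataclass(frozen=True)
class StationSeries:
    """Contiguous daily weather for one station.

    ``frame`` is indexed by a daily DatetimeIndex with columns
    ``tmean, tmin, precip, rh`` (rh may hold NaN for missing humidity).
    Use :meth:`from_frame` or :meth:`from_records` so the invariants
    (no calendar gaps, precip >= 0, tmin <= tmean, rh in [0, 100]) are
    checked on construction.
    """

    station_id: str
    latitude: float
    longitude: float
    elevation: float
    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        *,
        station_id: str,
        latitude: float,
        longitude: float = 0.0,
        elevation: float = 0.0,
    ) -> "StationSeries":
        f = frame.copy()
        if not isinstance(f.index, pd.DatetimeIndex):
            f.index = pd.to_datetime(f.index)
        f = f.sort_index()
        missing = [c for c in WEATHER_COLUMNS if c not in f.columns]
        if missing:
            raise DataValidationError(f"weather frame missing columns {missing}")
        f = f[list(WEATHER_COLUMNS)].astype(float)
        f.index.name = "date"
        idx = f.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0].date()
            raise DataValidationError(f"duplicate date {dup}")
        expected = pd.date_range(idx[0], idx[-1], freq="D")
        if len(expected) != len(idx):
            gap = expected.difference(idx)[0].date()
            raise CoverageError(f"missing calendar day {gap}")
        bad = f.index[f["precip"].to_numpy() < 0]
        if len(bad):
            raise DataValidationError(f"negative precipitation on {bad[0].date()}")
        bad = f.index[f["tmin"].to_numpy() > f["tmean"].to_numpy()]
        if len(bad):
            raise DataValidationError(f"tmin exceeds tmean on {bad[0].date()}")
        rh = f["rh"].to_numpy()
        with np.errstate(invalid="ignore"):
            bad_rh = f.index[(rh < 0) | (rh > 100)]
        if len(bad_rh):
            raise DataValidationError(f"rh outside [0, 100] on {bad_rh[0].date()}")
        return cls(
            station_id=station_id,
            latitude=latitude,
            longitude=longitude,
            elevation=elevation,
            frame=f,
        )

    @classmethod
    def from_records(
        cls,
        records: list[DailyRecord],
        *,
        station_id: str,
        latitude: float,
        longitude: float = 0.0,
        elevation: float = 0.0,
    ) -> "StationSeries":
        frame = pd.DataFrame(
            {
                "tmean": [r.tmean for r in records],
                "tmin": [r.tmin for r in records],
                "precip": [r.precip for r in records],
                "rh": [np.nan if r.rh is None else r.rh for r in records],
            },
            index=pd.to_datetime([r.date for r in records]),
        )
        return cls.from_frame(
            frame,
            station_id=station_id,
            latitude=latitude,
            longitude=longitude,
            elevation=elevation,
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def start_date(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end_date(self) -> dt.date:
        return self.frame.index[-1].date()

    def __len__(self) -> int:
        return len(self.frame)

    def covers(self, start: dt.date, end: dt.date) -> bool:
        return self.start_date <= start and end <= self.end_date

    def records(self) -> Iterator[DailyRecord]:
        """Iterate as DailyRecord objects (used by slow reference loops)."""
        dates = self.frame.index.date
        tmean = self.frame["tmean"].to_numpy()
        tmin = self.frame["tmin"].to_numpy()
        precip = self.frame["precip"].to_numpy()
        rh = self.frame["rh"].to_numpy()
        for i in range(len(dates)):
            yield DailyRecord(dates[i], float(tmean[i]), float(tmin[i]),
                              float(precip[i]), None if np.isnan(rh[i]) else float(rh[i]))


def slice_window(series: StationSeries, start: dt.date, end: dt.date) -> StationSeries:
    """Contiguous sub-series from ``start`` to ``end`` inclusive."""
    if start > end:
        raise DataValidationError(f"window start {start} after end {end}")
    if not series.covers(start, end):
        raise CoverageError(
            f"series covers {series.start_date}..{series.end_date}, "
            f"requested {start}..{end}"
        )
    sub = series.frame.loc[pd.Timestamp(start): pd.Timestamp(end)]
    return StationSeries(
        station_id=series.station_id,
        latitude=series.latitude,
        longitude=series.longitude,
        elevation=series.elevation,
        frame=sub,
    )


def annual_precip(series: StationSeries, year: int) -> float:
    """Total precipitation (mm) over the calendar year ``year``.

    Raises :class:`CoverageError` naming the missing range when the series
    does not span Jan 1 - Dec 31 of that year.
    """
    start, end = dt.date(year, 1, 1), dt.date(year, 12, 31)
    if not series.covers(start, end):
        raise CoverageError(
            f"annual precipitation for {year} needs {start}..{end}; "
            f"series covers {series.start_date}..{series.end_date}"
        )
    sub = series.frame.loc[pd.Timestamp(start): pd.Timestamp(end), "precip"]
    return float(sub.to_numpy().sum())
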