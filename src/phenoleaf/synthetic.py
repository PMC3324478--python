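"""Synthetic daily weather and leafing observations with known truth.

The generator emulates a continental monsoon climate of the kind found in
Northeast China: a sinusoidal annual temperature cycle (default annual
mean 4.5 deg C, seasonal amplitude 20.3 deg C, warmest around mid-July)
with AR(1) day-to-day anomalies, occurrence-times-gamma precipitation
whose monthly wet-day probabilities concentrate roughly three quarters of
the ~514 mm annual total in May-August, and Gaussian relative humidity.
A drier western-steppe preset (:meth:`ClimateConfig.semiarid`) is
provided for studies where spring water supply limits leafing.

Leafing observations are produced by running any of the six predictors
with known "truth" parameters on the generated weather and perturbing
the predicted day with rounded centred Gaussian noise, which is how the
calibration and validation machinery is exercised without access to real
station records.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .models import MODEL_BY_PARAMS, TPParams, predict, required_start_date
from .weather import LeafingObservation, StationSeries, days_in_year

__all__ = ["ClimateConfig", "TruthSpec", "generate_weather", "generate_leafing"]

# monthly wet-day probabilities tuned so ~77% of annual precipitation
# falls in May-August, as in a continental monsoon regime
_MONSOON_WET_PROB = (0.04, 0.04, 0.06, 0.12, 0.35, 0.50, 0.55, 0.50, 0.18, 0.08, 0.05, 0.04)


@dataclass(frozen=True)
class ClimateConfig:
    """Climate envelope for the weather generator.

    Defaults describe a moderate continental monsoon station (annual mean
    4.5 deg C, ~514 mm precipitation). ``ar1`` and ``resid_std`` control
    the persistence and size of daily temperature anomalies — persistence
    matters because accumulation models respond to runs of warm or cold
    days, not just to the mean.
    """

    mean_temp: float = 4.5        # deg C, annual mean
    amplitude: float = 20.3       # deg C, half the January-July range
    peak_doy: int = 197           # warmest day of year (mid-July)
    ar1: float = 0.7              # AR(1) coefficient of daily anomalies
    resid_std: float = 3.5        # deg C, innovation std of the anomalies
    tmin_offset_mean: float = 5.0  # deg C, mean diurnal drop tmean -> tmin
    tmin_offset_std: float = 1.5
    wet_prob: tuple[float, ...] = _MONSOON_WET_PROB  # per calendar month
    gamma_shape: float = 0.7      # wet-day amount ~ Gamma(shape, scale) mm
    gamma_scale: float = 9.6
    rh_mean: float = 60.0         # %, clipped to [5, 100]
    rh_std: float = 12.0
    latitude: float = 43.95
    longitude: float = 116.07
    elevation: float = 991.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise DataValidationError("amplitude must be >= 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise DataValidationError("ar1 must be in [0, 1)")
        if len(self.wet_prob) != 12 or any(not 0 <= p <= 1 for p in self.wet_prob):
            raise DataValidationError("wet_prob must be 12 probabilities in [0, 1]")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise DataValidationError("gamma shape and scale must be > 0")

    @classmethod
    def semiarid(cls) -> "ClimateConfig":
        """Western-steppe preset: ~300 mm yr^-1, slightly colder, drier air.

        Used for studies where the spring water supply frequently limits
        leaf-unfolding, as on the semi-arid steppe margin.
        """
        return cls(
            mean_temp=3.0,
            wet_prob=(0.02, 0.02, 0.04, 0.07, 0.20, 0.30, 0.33, 0.30, 0.10, 0.05, 0.03, 0.02),
            rh_mean=50.0,
        )


@dataclass(frozen=True)
class TruthSpec:
    """Ground-truth model and observation noise for synthetic leafing data."""

    params: object                # one of the model parameter objects
    noise_std: float = 1.0        # days; observations are rounded to integers

    def __post_init__(self):
        if self.noise_std < 0:
            raise DataValidationError("noise_std must be >= 0")
        if type(self.params) not in MODEL_BY_PARAMS:
            raise DataValidationError(f"unrecognised parameter object {self.params!r}")

    @property
    def model(self) -> str:
        return MODEL_BY_PARAMS[type(self.params)]

    @classmethod
    def water_limited(cls, noise_std: float = 1.0) -> "TruthSpec":
        """TP truth whose hydrological threshold binds in a substantial
        fraction of years (roughly a third to a half) when paired with
        :meth:`ClimateConfig.semiarid` — the regime in which precipitation,
        not temperature alone, sets the leafing date."""
        return cls(
            params=TPParams(T_b=5.0, F_star=120.0, k1=0.04, k2=0.4, P_crit=32.0),
            noise_std=noise_std,
        )


def generate_weather(
    cfg: ClimateConfig,
    start_year: int,
    n_years: int,
    seed: int,
    station_id: str = "synthetic",
) -> StationSeries:
    """Generate ``n_years`` of contiguous daily weather from Jan 1 of
    ``start_year``. Fully reproducible for a given seed."""
    if n_years < 2:
        raise DataValidationError("need n_years >= 2 (models use previous-year weather)")
    rng = np.random.default_rng(seed)
    index = pd.date_range(
        dt.date(start_year, 1, 1), dt.date(start_year + n_years - 1, 12, 31), freq="D"
    )
    n = len(index)
    doy = index.dayofyear.to_numpy(dtype=float)
    month = index.month.to_numpy()

    climatology = cfg.mean_temp + cfg.amplitude * np.cos(
        2.0 * np.pi * (doy - cfg.peak_doy) / 365.25
    )
    # AR(1) anomalies, stationary start
    innov = rng.normal(0.0, cfg.resid_std, n)
    anom = np.empty(n)
    stat_std = cfg.resid_std / np.sqrt(1.0 - cfg.ar1**2) if cfg.ar1 > 0 else cfg.resid_std
    anom[0] = rng.normal(0.0, stat_std)
    for i in range(1, n):
        anom[i] = cfg.ar1 * anom[i - 1] + innov[i]
    tmean = climatology + anom
    tmin = tmean - np.abs(rng.normal(cfg.tmin_offset_mean, cfg.tmin_offset_std, n))

    wet_p = np.asarray(cfg.wet_prob)[month - 1]
    wet = rng.random(n) < wet_p
    precip = np.where(wet, rng.gamma(cfg.gamma_shape, cfg.gamma_scale, n), 0.0)
    rh = np.clip(rng.normal(cfg.rh_mean, cfg.rh_std, n), 5.0, 100.0)

    frame = pd.DataFrame(
        {"tmean": tmean, "tmin": tmin, "precip": precip, "rh": rh}, index=index
    )
    return StationSeries.from_frame(
        frame,
        station_id=station_id,
        latitude=cfg.latitude,
        longitude=cfg.longitude,
        elevation=cfg.elevation,
    )


def generate_leafing(
    series: StationSeries,
    truth: TruthSpec,
    seed: int,
    species: str = "synthetic-species",
) -> list[LeafingObservation]:
    """One observation per usable year: truth-model prediction plus rounded
    Gaussian noise, clipped to [1, days-in-year].

    Years whose required weather lookback precedes the series (typically
    the first year, for models needing previous-year data) are skipped.
    A year in which the truth model never reaches its thresholds raises a
    generation error naming the year — the caller should adjust the truth
    parameters rather than silently drop years.
    """
    rng = np.random.default_rng(seed)
    observations: list[LeafingObservation] = []
    for year in range(series.start_date.year, series.end_date.year + 1):
        if not series.covers(dt.date(year, 1, 1), dt.date(year, 12, 31)):
            continue
        if series.start_date > required_start_date(truth.params, year):
            continue
        pred = predict(series, truth.params, year)
        if pred.leafing_doy is None:
            raise DataValidationError(
                f"truth model {truth.model} reached no leafing date in {year}; "
                "adjust the truth parameters"
            )
        noisy = int(round(pred.leafing_doy + rng.normal(0.0, truth.noise_std)))
        doy = int(np.clip(noisy, 1, days_in_year(year)))
        observations.append(
            LeafingObservation(
                station_id=series.station_id, species=species, year=year, leafing_doy=doy
            )
        )
    return observations
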