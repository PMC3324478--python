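import datetime as dt

import numpy as np
import pandas as pd
import pytest

from phenoleaf import ClimateConfig, StationSeries, generate_weather
from phenoleaf.models import (
    AMParams,
    GSIParams,
    PMParams,
    SMParams,
    StartDateSpec,
    SWParams,
    TPParams,
)

N_RANDOM_CASES = 100


def constant_series(
    tmean: float,
    precip: float = 0.0,
    years=(2000, 2001),
    tmin_offset: float = 5.0,
    rh: float = 70.0,
    latitude: float = 45.0,
) -> StationSeries:
    """Two-plus years of identical weather for closed-form checks."""
    index = pd.date_range(dt.date(years[0], 1, 1), dt.date(years[-1], 12, 31), freq="D")
    frame = pd.DataFrame(
        {
            "tmean": tmean,
            "tmin": tmean - tmin_offset,
            "precip": precip,
            "rh": rh,
        },
        index=index,
    )
    return StationSeries.from_frame(frame, station_id="const", latitude=latitude)


def series_from_arrays(tmean, precip, years=(2000, 2001), rh=70.0, latitude=45.0,
                       tmin_offset=5.0):
    index = pd.date_range(dt.date(years[0], 1, 1), dt.date(years[-1], 12, 31), freq="D")
    tmean = np.broadcast_to(np.asarray(tmean, dtype=float), len(index))
    precip = np.broadcast_to(np.asarray(precip, dtype=float), len(index))
    frame = pd.DataFrame(
        {"tmean": tmean, "tmin": tmean - tmin_offset, "precip": precip, "rh": rh},
        index=index,
    )
    return StationSeries.from_frame(frame, station_id="arr", latitude=latitude)


def shift_temperature(series: StationSeries, delta: float) -> StationSeries:
    frame = series.frame.copy()
    frame["tmean"] += delta
    frame["tmin"] += delta
    return StationSeries.from_frame(
        frame,
        station_id=series.station_id,
        latitude=series.latitude,
        longitude=series.longitude,
        elevation=series.elevation,
    )


def add_precip(series: StationSeries, day: dt.date, amount: float) -> StationSeries:
    frame = series.frame.copy()
    frame.loc[pd.Timestamp(day), "precip"] += amount
    return StationSeries.from_frame(
        frame,
        station_id=series.station_id,
        latitude=series.latitude,
        longitude=series.longitude,
        elevation=series.elevation,
    )


@pytest.fixture(scope="session")
def monsoon_series():
    """Three years of default continental-monsoon weather."""
    return generate_weather(ClimateConfig(), 2000, 3, seed=101)


@pytest.fixture(scope="session")
def random_cases():
    """Random two-year weather series with cached record lists.

    Alternates the default and semi-arid climates so precipitation-driven
    behaviour is exercised on both wet and dry regimes.
    """
    cases = []
    for i in range(N_RANDOM_CASES):
        cfg = ClimateConfig() if i % 2 == 0 else ClimateConfig.semiarid()
        series = generate_weather(cfg, 2000, 2, seed=1000 + i)
        cases.append((series, list(series.records())))
    return cases


def random_params(model: str, rng: np.random.Generator):
    """Admissible random parameters spanning realistic ranges per model."""
    t0_choice = rng.random()
    if model in ("SW", "TP"):
        t0 = StartDateSpec.jan1() if t0_choice < 0.7 else StartDateSpec.from_offset(
            int(rng.integers(0, 303))
        )
    else:
        t0 = StartDateSpec.sep1_prev() if t0_choice < 0.7 else StartDateSpec.from_offset(
            int(rng.integers(0, 200))
        )
    if model == "SW":
        return SWParams(T_b=rng.uniform(0, 10), F_star=rng.uniform(20, 400), t0=t0)
    if model == "TP":
        return TPParams(
            T_b=rng.uniform(0, 10),
            F_star=rng.uniform(20, 400),
            k1=rng.uniform(0, 0.1),
            k2=rng.uniform(0, 0.8),
            P_crit=rng.uniform(0, 50),
            t0=t0,
        )
    if model == "SM":
        return SMParams(
            T_b=rng.uniform(0, 8),
            C_star=rng.uniform(0, 40),
            F_star=rng.uniform(10, 250),
            T_o=rng.uniform(-1, 8),
            t0=t0,
        )
    if model == "PM":
        return PMParams(
            C_star=rng.uniform(0, 40),
            F_star=rng.uniform(50, 450),
            K_m=rng.uniform(0, 1),
            T_o=rng.uniform(-1, 8),
            t0=t0,
        )
    if model == "AM":
        return AMParams(
            T_b=rng.uniform(0, 10),
            C_star=rng.uniform(0, 60),
            a=rng.uniform(50, 500),
            b=rng.uniform(-0.1, 0.05),
            t0=t0,
        )
    if model == "GSI":
        return GSIParams(
            threshold=rng.uniform(0.15, 0.8),
            window=int(rng.integers(5, 30)),
        )
    raise ValueError(model)
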