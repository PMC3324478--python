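"""Readers and writers for the package's file surfaces.

Weather CSV dialect: header ``date,tmean,tmin,precip,rh``, ISO-8601
dates, one row per calendar day; an empty field means missing, and only
``rh`` may be missing. Phenology CSV: ``station_id,species,year,
leafing_doy``. Model parameters serialize to JSON as
``{"model": "TP", "t0": {"mode": "fixed", "month_day": "01-01",
"year_offset": 0}, "T_b": ..., ...}``. Climate and annealing
configurations load from YAML mappings whose keys mirror the dataclass
fields.

Numeric CSV output uses pandas' shortest round-trip representation, so a
write-then-read cycle reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataValidationError
from .fitting import AnnealConfig
from .models import PARAMS_BY_MODEL, MODEL_BY_PARAMS, StartDateSpec
from .synthetic import ClimateConfig, TruthSpec
from .weather import LeafingObservation, StationSeries

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "read_phenology_csv",
    "write_phenology_csv",
    "read_station_csv",
    "params_to_dict",
    "params_from_dict",
    "write_params_json",
    "read_params_json",
    "load_climate_yaml",
    "load_truth_yaml",
    "load_anneal_yaml",
]

WEATHER_HEADER = ["date", "tmean", "tmin", "precip", "rh"]
PHENOLOGY_HEADER = ["station_id", "species", "year", "leafing_doy"]
STATION_HEADER = ["station_id", "latitude", "longitude", "elevation"]


def read_weather_csv(
    path,
    *,
    station_id: str = "station",
    latitude: float = 45.0,
    longitude: float = 125.0,
    elevation: float = 200.0,
) -> StationSeries:
    """Read a daily weather CSV into a validated StationSeries.

    Gaps, negative precipitation and out-of-range humidity are reported
    with the offending date; a malformed date or a missing non-rh value
    is reported with its line number.
    """
    frame = pd.read_csv(path)
    if list(frame.columns) != WEATHER_HEADER:
        raise DataValidationError(
            f"{path}: expected header {','.join(WEATHER_HEADER)}, got "
            f"{','.join(map(str, frame.columns))}"
        )
    try:
        idx = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"{path}: unparseable date ({exc})") from exc
    for col in ("tmean", "tmin", "precip"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise DataValidationError(
                f"{path}: missing or non-numeric {col} on line {bad[0] + 2}"
            )
        frame[col] = vals
    frame["rh"] = pd.to_numeric(frame["rh"], errors="coerce")
    frame = frame.set_index(idx).drop(columns=["date"])
    return StationSeries.from_frame(
        frame,
        station_id=station_id,
        latitude=latitude,
        longitude=longitude,
        elevation=elevation,
    )


def write_weather_csv(series: StationSeries, path) -> None:
    frame = series.frame.copy()
    frame.insert(0, "date", frame.index.strftime("%Y-%m-%d"))
    frame.to_csv(path, index=False)


def read_phenology_csv(path) -> list[LeafingObservation]:
    """Read leafing observations; duplicate (station, species, year) rejected."""
    frame = pd.read_csv(path)
    if list(frame.columns) != PHENOLOGY_HEADER:
        raise DataValidationError(
            f"{path}: expected header {','.join(PHENOLOGY_HEADER)}, got "
            f"{','.join(map(str, frame.columns))}"
        )
    observations = []
    seen = set()
    for line, row in enumerate(frame.itertuples(index=False), start=2):
        key = (row.station_id, row.species, int(row.year))
        if key in seen:
            raise DataValidationError(f"{path}: duplicate observation {key} on line {line}")
        seen.add(key)
        try:
            obs = LeafingObservation(
                station_id=str(row.station_id),
                species=str(row.species),
                year=int(row.year),
                leafing_doy=int(row.leafing_doy),
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path}: line {line}: {exc}") from exc
        observations.append(obs)
    return observations


def write_phenology_csv(observations: list[LeafingObservation], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "station_id": o.station_id,
                "species": o.species,
                "year": o.year,
                "leafing_doy": o.leafing_doy,
            }
            for o in observations
        ],
        columns=PHENOLOGY_HEADER,
    )
    frame.to_csv(path, index=False)


def read_station_csv(path) -> dict[str, dict[str, float]]:
    """Station metadata keyed by station_id."""
    frame = pd.read_csv(path)
    if list(frame.columns) != STATION_HEADER:
        raise DataValidationError(
            f"{path}: expected header {','.join(STATION_HEADER)}"
        )
    return {
        str(row.station_id): {
            "latitude": float(row.latitude),
            "longitude": float(row.longitude),
            "elevation": float(row.elevation),
        }
        for row in frame.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# parameter JSON


def _t0_to_dict(t0: StartDateSpec) -> dict:
    if t0.mode == "parameterized":
        return {"mode": "parameterized", "offset_days": t0.offset_days}
    return {
        "mode": "fixed",
        "month_day": f"{t0.month:02d}-{t0.day:02d}",
        "year_offset": t0.year_offset,
    }


def _t0_from_dict(d: dict) -> StartDateSpec:
    if d["mode"] == "parameterized":
        return StartDateSpec.from_offset(int(d["offset_days"]))
    month, day = (int(x) for x in d["month_day"].split("-"))
    return StartDateSpec(mode="fixed", month=month, day=day,
                         year_offset=int(d.get("year_offset", 0)))


def params_to_dict(params) -> dict:
    model = MODEL_BY_PARAMS[type(params)]
    out = {"model": model}
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        out[f.name] = _t0_to_dict(value) if f.name == "t0" else value
    return out


def params_from_dict(d: dict):
    d = dict(d)
    model = d.pop("model")
    if model not in PARAMS_BY_MODEL:
        raise DataValidationError(f"unknown model {model!r}")
    if "t0" in d:
        d["t0"] = _t0_from_dict(d["t0"])
    return PARAMS_BY_MODEL[model](**d)


def write_params_json(params, path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params), indent=2) + "\n")


def read_params_json(path):
    return params_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# YAML configuration


def load_climate_yaml(path) -> ClimateConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "wet_prob" in raw:
        raw["wet_prob"] = tuple(raw["wet_prob"])
    return ClimateConfig(**raw)


def load_truth_yaml(path) -> TruthSpec:
    """Truth spec YAML: a ``params`` mapping in the parameter-JSON schema
    plus an optional ``noise_std``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    params = params_from_dict(raw["params"])
    return TruthSpec(params=params, noise_std=float(raw.get("noise_std", 1.0)))


def load_anneal_yaml(path, seed: int | None = None) -> AnnealConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        raw["seed"] = seed
    if "seed" not in raw:
        raise DataValidationError("annealing config requires a seed")
    return AnnealConfig(**raw)
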