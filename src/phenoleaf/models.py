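"""Six spring leaf-unfolding predictors.

Each predictor maps a :class:`~phenoleaf.weather.StationSeries` plus a
parameter object to the predicted leaf-unfolding day of one calendar year:

* SW  — spring warming: growing-degree-day sum above a base temperature
  from a starting date t0 (default Jan 1) until a critical sum F*.
* TP  — temperature-precipitation: SW's thermal condition combined with a
  hydrological condition k1*P_b + k2*sum(R_i) >= P_crit, where P_b is the
  previous year's annual precipitation and R_i the current-year daily
  precipitation accumulated from t0. Leafing is the first day on which
  both conditions hold.
* SM  — sequential: chilling (triangular response) accumulates from t0
  (default Sep 1 of the previous year) until the chilling requirement C*
  is met on day t1; sigmoid forcing then accumulates (zero at or below
  the base temperature) until F*.
* PM  — parallel: chilling and forcing accumulate simultaneously; the
  forcing contribution is scaled by a bud competence that rises linearly
  from K_m to 1 as chilling approaches C*.
* AM  — alternating: chill days (tmean below T_b) relax the forcing
  requirement exponentially, F*(S_c) = a * exp(b * S_c); leafing when the
  degree-day sum reaches the moving target and S_c >= C*.
* GSI — growing season index: trailing mean of the product of minimum-
  temperature, vapour-pressure-deficit and photoperiod ramp indicators,
  evaluated from Jan 1; leafing when the index reaches a threshold.

Accumulation sums include both the starting day and the candidate day;
the leafing day is the first day on which the inequality holds (>=).
A crossing that never happens by Dec 31 yields ``leafing_doy = None``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CoverageError, DataValidationError, InvalidParameterError
from .weather import StationSeries, compute_photoperiod, compute_vpd

__all__ = [
    "StartDateSpec",
    "SWParams",
    "TPParams",
    "SMParams",
    "PMParams",
    "AMParams",
    "GSIParams",
    "Prediction",
    "forcing_gdd",
    "forcing_sigmoid",
    "chilling_triangular",
    "ramp",
    "predict_sw",
    "predict_tp",
    "predict_sm",
    "predict_pm",
    "predict_am",
    "predict_gsi",
    "predict",
    "required_start_date",
    "MODEL_NAMES",
    "PARAMS_BY_MODEL",
    "MODEL_BY_PARAMS",
    "CHUINE_T_LOW",
    "CHUINE_T_HIGH",
    "CHUINE_VA",
    "CHUINE_VB",
    "CHUINE_VC",
]

# Fixed chilling/forcing response constants from the European
# parameterisation tradition (Chuine et al.), used by SM/PM when only a
# subset of parameters is estimated.
CHUINE_T_LOW = -3.4
CHUINE_T_HIGH = 10.4
CHUINE_VA = 28.4
CHUINE_VB = -0.185
CHUINE_VC = -18.4

MODEL_NAMES = ("SW", "TP", "SM", "PM", "AM", "GSI")


# ---------------------------------------------------------------------------
# starting dates


@dataclass(frozen=True)
class StartDateSpec:
    """Starting date of accumulation, fixed or searched by the calibrator.

    A fixed spec names a month/day and a year offset (0 = leafing year,
    -1 = previous year). A parameterized spec carries ``offset_days``,
    the integer day offset from Sep 1 of the previous year, which the
    fitting layer searches over.
    """

    mode: str = "fixed"  # "fixed" | "parameterized"
    month: int = 1
    day: int = 1
    year_offset: int = 0
    offset_days: int | None = None

    def __post_init__(self):
        if self.mode not in ("fixed", "parameterized"):
            raise InvalidParameterError(f"unknown start-date mode {self.mode!r}")
        if self.mode == "parameterized" and self.offset_days is None:
            raise InvalidParameterError("parameterized start date requires offset_days")

    def resolve(self, year: int) -> dt.date:
        """Concrete calendar date for a given leafing year."""
        if self.offset_days is not None:
            return dt.date(year - 1, 9, 1) + dt.timedelta(days=int(self.offset_days))
        return dt.date(year + self.year_offset, self.month, self.day)

    @classmethod
    def jan1(cls) -> "StartDateSpec":
        return cls(mode="fixed", month=1, day=1, year_offset=0)

    @classmethod
    def sep1_prev(cls) -> "StartDateSpec":
        return cls(mode="fixed", month=9, day=1, year_offset=-1)

    @classmethod
    def from_offset(cls, offset_days: int) -> "StartDateSpec":
        return cls(mode="parameterized", offset_days=int(offset_days))


# ---------------------------------------------------------------------------
# parameter objects


@dataclass(frozen=True)
class SWParams:
    T_b: float
    F_star: float
    t0: StartDateSpec = field(default_factory=StartDateSpec.jan1)

    def __post_init__(self):
        if self.F_star < 0:
            raise InvalidParameterError(f"F_star must be >= 0, got {self.F_star}")


@dataclass(frozen=True)
class TPParams:
    T_b: float
    F_star: float
    k1: float
    k2: float
    P_crit: float
    t0: StartDateSpec = field(default_factory=StartDateSpec.jan1)

    def __post_init__(self):
        if self.F_star < 0:
            raise InvalidParameterError(f"F_star must be >= 0, got {self.F_star}")
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidParameterError("k1 and k2 must be >= 0")
        if self.P_crit < 0:
            raise InvalidParameterError(f"P_crit must be >= 0, got {self.P_crit}")


@dataclass(frozen=True)
class SMParams:
    T_b: float
    C_star: float
    F_star: float
    T_o: float
    T_low: float = CHUINE_T_LOW
    T_high: float = CHUINE_T_HIGH
    va: float = CHUINE_VA
    vb: float = CHUINE_VB
    vc: float = CHUINE_VC
    t0: StartDateSpec = field(default_factory=StartDateSpec.sep1_prev)

    def __post_init__(self):
        if not self.T_low < self.T_o < self.T_high:
            raise InvalidParameterError(
                f"need T_low < T_o < T_high, got {self.T_low}, {self.T_o}, {self.T_high}"
            )
        if self.C_star < 0 or self.F_star < 0:
            raise InvalidParameterError("C_star and F_star must be >= 0")
        if self.va <= 0:
            raise InvalidParameterError(f"va must be > 0, got {self.va}")


@dataclass(frozen=True)
class PMParams:
    C_star: float
    F_star: float
    K_m: float
    T_o: float
    T_low: float = CHUINE_T_LOW
    T_high: float = CHUINE_T_HIGH
    va: float = CHUINE_VA
    vb: float = CHUINE_VB
    vc: float = CHUINE_VC
    t0: StartDateSpec = field(default_factory=StartDateSpec.sep1_prev)

    def __post_init__(self):
        if not 0.0 <= self.K_m <= 1.0:
            raise InvalidParameterError(f"K_m must be in [0, 1], got {self.K_m}")
        if not self.T_low < self.T_o < self.T_high:
            raise InvalidParameterError(
                f"need T_low < T_o < T_high, got {self.T_low}, {self.T_o}, {self.T_high}"
            )
        if self.C_star < 0 or self.F_star < 0:
            raise InvalidParameterError("C_star and F_star must be >= 0")
        if self.va <= 0:
            raise InvalidParameterError(f"va must be > 0, got {self.va}")


@dataclass(frozen=True)
class AMParams:
    T_b: float
    C_star: float
    a: float
    b: float
    t0: StartDateSpec = field(default_factory=StartDateSpec.sep1_prev)

    def __post_init__(self):
        if self.a <= 0:
            raise InvalidParameterError(f"a must be > 0, got {self.a}")
        if self.C_star < 0:
            raise InvalidParameterError(f"C_star must be >= 0, got {self.C_star}")


@dataclass(frozen=True)
class GSIParams:
    """Ramp bounds, window and threshold for the growing season index.

    Defaults follow the GSI source model: tmin ramp -2..5 deg C, VPD ramp
    4100..900 Pa (wetter is better, hence decreasing), photoperiod ramp
    36000..39600 s (10 h to 11 h), 21-day trailing mean, threshold 0.5.
    The threshold is configurable because 0.5 tends to be too low for
    continental climates.
    """

    tmin_lo: float = -2.0
    tmin_hi: float = 5.0
    vpd_lo: float = 900.0
    vpd_hi: float = 4100.0
    photo_lo: float = 36000.0
    photo_hi: float = 39600.0
    window: int = 21
    threshold: float = 0.5

    def __post_init__(self):
        for lo, hi, name in (
            (self.tmin_lo, self.tmin_hi, "tmin"),
            (self.vpd_lo, self.vpd_hi, "vpd"),
            (self.photo_lo, self.photo_hi, "photo"),
        ):
            if not lo < hi:
                raise InvalidParameterError(f"{name} ramp requires lo < hi, got {lo}, {hi}")
        if self.window < 1:
            raise InvalidParameterError(f"window must be >= 1, got {self.window}")
        if not 0.0 < self.threshold <= 1.0:
            raise InvalidParameterError(f"threshold must be in (0, 1], got {self.threshold}")


PARAMS_BY_MODEL = {
    "SW": SWParams,
    "TP": TPParams,
    "SM": SMParams,
    "PM": PMParams,
    "AM": AMParams,
    "GSI": GSIParams,
}
MODEL_BY_PARAMS = {cls: name for name, cls in PARAMS_BY_MODEL.items()}


@dataclass(frozen=True)
class Prediction:
    """Predicted leafing day for one year.

    ``leafing_doy`` is the 1-based day-of-year of the leafing year, or
    None when the required threshold(s) are not reached by Dec 31.
    ``reached_thermal`` reports the thermal (or index) condition;
    ``reached_hydro`` is set only by the TP model.
    """

    year: int
    leafing_doy: int | None
    reached_thermal: bool
    reached_hydro: bool | None = None

    @property
    def reached(self) -> bool:
        return self.leafing_doy is not None


# ---------------------------------------------------------------------------
# daily rate functions


def forcing_gdd(tmean, T_b):
    """Growing-degree-day forcing: max(0, tmean - T_b), deg C day."""
    out = np.maximum(0.0, np.asarray(tmean, dtype=float) - T_b)
    return float(out) if np.isscalar(tmean) else out


def forcing_sigmoid(tmean, va, vb, vc):
    """Sigmoid forcing rate va / (1 + exp(vb * (tmean + vc))), forcing units.

    With vb < 0 this rises from 0 towards va; the midpoint va/2 sits at
    tmean = -vc.
    """
    t = np.asarray(tmean, dtype=float)
    out = va / (1.0 + np.exp(vb * (t + vc)))
    return float(out) if np.isscalar(tmean) else out


def chilling_triangular(tmean, T_low, T_o, T_high):
    """Triangular chilling rate: 0 at/below T_low and at/above T_high,
    1 at the optimum T_o, linear in between. Chill units per day."""
    t = np.asarray(tmean, dtype=float)
    up = (t - T_low) / (T_o - T_low)
    down = (T_high - t) / (T_high - T_o)
    out = np.clip(np.minimum(up, down), 0.0, 1.0)
    return float(out) if np.isscalar(tmean) else out


def ramp(x, lo, hi, *, decreasing: bool = False):
    """Linear 0..1 ramp between lo and hi (reversed when decreasing)."""
    v = np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    if decreasing:
        v = 1.0 - v
    return float(v) if np.isscalar(x) else v


# ---------------------------------------------------------------------------
# per-year evaluation context


@dataclass(frozen=True)
class YearContext:
    """Numpy view of the weather window needed to predict one year.

    Arrays run from ``start`` (Jan 1 of the previous year when the series
    reaches back that far, otherwise the series start) through Dec 31 of
    the leafing year. ``jan1_index``
    locates Jan 1 of the leafing year inside the arrays, so a crossing at
    array index i corresponds to DOY ``i - jan1_index + 1``.
    """

    year: int
    start: dt.date
    jan1_index: int
    tmean: np.ndarray = field(repr=False)
    tmin: np.ndarray = field(repr=False)
    precip: np.ndarray = field(repr=False)
    rh: np.ndarray = field(repr=False)
    latitude: float
    prev_annual_precip: float | None

    def index_of(self, day: dt.date) -> int:
        return (day - self.start).days

    def doy_of_index(self, i: int) -> int:
        return i - self.jan1_index + 1


def build_year_context(series: StationSeries, year: int) -> YearContext:
    """Extract the arrays needed to predict leafing in ``year``.

    Requires coverage of at least Jan 1 - Dec 31 of the leafing year;
    reaches back to Jan 1 of the previous year when available, and
    records the previous calendar year's total precipitation when the
    series covers it completely (needed by TP).
    """
    jan1 = dt.date(year, 1, 1)
    dec31 = dt.date(year, 12, 31)
    if not series.covers(jan1, dec31):
        raise CoverageError(
            f"predicting year {year} needs {jan1}..{dec31}; series covers "
            f"{series.start_date}..{series.end_date}"
        )
    # reach back as far as Jan 1 of the previous year (covers every t0 the
    # fitting layer can propose, and the TP previous-year precipitation)
    start = max(series.start_date, dt.date(year - 1, 1, 1))
    if series.covers(dt.date(year - 1, 1, 1), dt.date(year - 1, 12, 31)):
        prev = series.frame.loc[
            pd.Timestamp(dt.date(year - 1, 1, 1)): pd.Timestamp(dt.date(year - 1, 12, 31)),
            "precip",
        ]
        prev_annual = float(prev.to_numpy().sum())
    else:
        prev_annual = None
    sub = series.frame.loc[pd.Timestamp(start): pd.Timestamp(dec31)]
    return YearContext(
        year=year,
        start=start,
        jan1_index=(jan1 - start).days,
        tmean=sub["tmean"].to_numpy(),
        tmin=sub["tmin"].to_numpy(),
        precip=sub["precip"].to_numpy(),
        rh=sub["rh"].to_numpy(),
        latitude=series.latitude,
        prev_annual_precip=prev_annual,
    )


def _first_crossing(csum: np.ndarray, threshold: float) -> int | None:
    """First index where the non-decreasing cumulative sum reaches threshold."""
    i = int(np.searchsorted(csum, threshold, side="left"))
    return i if i < len(csum) else None


def _resolve_start_index(ctx: YearContext, t0: StartDateSpec) -> int:
    start = t0.resolve(ctx.year)
    s = ctx.index_of(start)
    if s < 0:
        raise CoverageError(
            f"start date {start} precedes available window beginning {ctx.start}"
        )
    if start > dt.date(ctx.year, 12, 31):
        raise InvalidParameterError(f"start date {start} is after Dec 31 of {ctx.year}")
    return s


# ---------------------------------------------------------------------------
# predictors (array kernels + public series-level wrappers)


def _predict_sw_ctx(ctx: YearContext, p: SWParams) -> Prediction:
    s = _resolve_start_index(ctx, p.t0)
    csum = np.cumsum(forcing_gdd(ctx.tmean[s:], p.T_b))
    i = _first_crossing(csum, p.F_star)
    if i is None:
        return Prediction(ctx.year, None, reached_thermal=False)
    return Prediction(ctx.year, ctx.doy_of_index(s + i), reached_thermal=True)


def _predict_tp_ctx(ctx: YearContext, p: TPParams) -> Prediction:
    if ctx.prev_annual_precip is None:
        raise CoverageError(
            f"TP needs the complete previous calendar year ({ctx.year - 1}) "
            "for the annual precipitation P_b"
        )
    s = _resolve_start_index(ctx, p.t0)
    thermal = np.cumsum(forcing_gdd(ctx.tmean[s:], p.T_b))
    hydro = p.k1 * ctx.prev_annual_precip + p.k2 * np.cumsum(ctx.precip[s:])
    it = _first_crossing(thermal, p.F_star)
    ih = _first_crossing(hydro, p.P_crit)
    if it is None or ih is None:
        return Prediction(ctx.year, None, reached_thermal=it is not None,
                          reached_hydro=ih is not None)
    return Prediction(ctx.year, ctx.doy_of_index(s + max(it, ih)),
                      reached_thermal=True, reached_hydro=True)


def _predict_sm_ctx(ctx: YearContext, p: SMParams) -> Prediction:
    s = _resolve_start_index(ctx, p.t0)
    t = ctx.tmean[s:]
    chill = np.cumsum(chilling_triangular(t, p.T_low, p.T_o, p.T_high))
    t1 = _first_crossing(chill, p.C_star)
    if t1 is None:
        return Prediction(ctx.year, None, reached_thermal=False)
    rate = forcing_sigmoid(t[t1:], p.va, p.vb, p.vc)
    rate = np.where(t[t1:] > p.T_b, rate, 0.0)
    sf = np.cumsum(rate)
    i = _first_crossing(sf, p.F_star)
    if i is None:
        return Prediction(ctx.year, None, reached_thermal=False)
    return Prediction(ctx.year, ctx.doy_of_index(s + t1 + i), reached_thermal=True)


def _predict_pm_ctx(ctx: YearContext, p: PMParams) -> Prediction:
    s = _resolve_start_index(ctx, p.t0)
    t = ctx.tmean[s:]
    chill = np.cumsum(chilling_triangular(t, p.T_low, p.T_o, p.T_high))
    if p.C_star == 0:
        competence = np.ones_like(chill)
    else:
        # competence uses the chilling state including the current day
        competence = p.K_m + (1.0 - p.K_m) * np.minimum(chill / p.C_star, 1.0)
    sf = np.cumsum(competence * forcing_sigmoid(t, p.va, p.vb, p.vc))
    i = _first_crossing(sf, p.F_star)
    if i is None:
        return Prediction(ctx.year, None, reached_thermal=False)
    return Prediction(ctx.year, ctx.doy_of_index(s + i), reached_thermal=True)


def _predict_am_ctx(ctx: YearContext, p: AMParams) -> Prediction:
    s = _resolve_start_index(ctx, p.t0)
    t = ctx.tmean[s:]
    sc = np.cumsum(t < p.T_b)
    sf = np.cumsum(forcing_gdd(t, p.T_b))
    ok = (sc >= p.C_star) & (sf >= p.a * np.exp(p.b * sc))
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return Prediction(ctx.year, None, reached_thermal=False)
    return Prediction(ctx.year, ctx.doy_of_index(s + int(idx[0])), reached_thermal=True)


def _predict_gsi_ctx(ctx: YearContext, p: GSIParams) -> Prediction:
    j = ctx.jan1_index
    tmin = ctx.tmin[j:]
    rh = ctx.rh[j:]
    if np.any(np.isnan(rh)):
        bad_doy = int(np.flatnonzero(np.isnan(rh))[0]) + 1
        raise DataValidationError(
            f"GSI needs relative humidity for every day of {ctx.year}; "
            f"missing from DOY {bad_doy}"
        )
    tmean = ctx.tmean[j:]
    doys = np.arange(1, len(tmin) + 1, dtype=float)
    vpd = compute_vpd(tmean, rh)
    photo = compute_photoperiod(ctx.latitude, doys)
    igsi = (
        ramp(tmin, p.tmin_lo, p.tmin_hi)
        * ramp(vpd, p.vpd_lo, p.vpd_hi, decreasing=True)
        * ramp(photo, p.photo_lo, p.photo_hi)
    )
    # trailing mean over min(window, days since Jan 1)
    csum = np.concatenate(([0.0], np.cumsum(igsi)))
    n = len(igsi)
    lengths = np.minimum(np.arange(1, n + 1), p.window)
    gsi = (csum[1:] - csum[np.arange(1, n + 1) - lengths]) / lengths
    idx = np.flatnonzero(gsi >= p.threshold)
    if len(idx) == 0:
        return Prediction(ctx.year, None, reached_thermal=False)
    return Prediction(ctx.year, int(idx[0]) + 1, reached_thermal=True)


_KERNELS = {
    "SW": _predict_sw_ctx,
    "TP": _predict_tp_ctx,
    "SM": _predict_sm_ctx,
    "PM": _predict_pm_ctx,
    "AM": _predict_am_ctx,
    "GSI": _predict_gsi_ctx,
}


def predict_from_context(ctx: YearContext, params) -> Prediction:
    """Run the predictor matching ``type(params)`` on a prebuilt context."""
    name = MODEL_BY_PARAMS[type(params)]
    return _KERNELS[name](ctx, params)


def _series_predict(series: StationSeries, params, year: int) -> Prediction:
    ctx = build_year_context(series, year)
    return predict_from_context(ctx, params)


def predict_sw(series: StationSeries, params: SWParams, year: int) -> Prediction:
    """Spring warming model prediction for one year."""
    return _series_predict(series, params, year)


def predict_tp(series: StationSeries, params: TPParams, year: int) -> Prediction:
    """Temperature-precipitation model prediction for one year."""
    return _series_predict(series, params, year)


def predict_sm(series: StationSeries, params: SMParams, year: int) -> Prediction:
    """Sequential (chilling-then-forcing) model prediction for one year."""
    return _series_predict(series, params, year)


def predict_pm(series: StationSeries, params: PMParams, year: int) -> Prediction:
    """Parallel (simultaneous chilling/forcing) model prediction."""
    return _series_predict(series, params, year)


def predict_am(series: StationSeries, params: AMParams, year: int) -> Prediction:
    """Alternating model prediction (chill days relax the forcing target)."""
    return _series_predict(series, params, year)


def predict_gsi(series: StationSeries, params: GSIParams, year: int) -> Prediction:
    """Growing-season-index threshold crossing prediction."""
    return _series_predict(series, params, year)


def predict(series: StationSeries, params, year: int) -> Prediction:
    """Dispatch on the parameter type; accepts any of the six models."""
    return _series_predict(series, params, year)


def required_start_date(params, year: int) -> dt.date:
    """Earliest weather date a model needs to predict ``year``."""
    if isinstance(params, TPParams):
        return min(dt.date(year - 1, 1, 1), params.t0.resolve(year))
    if isinstance(params, GSIParams):
        return dt.date(year, 1, 1)
    return params.t0.resolve(year)


def with_start(params, t0: StartDateSpec):
    """Copy of a parameter object with a different starting date."""
    if isinstance(params, GSIParams):
        raise InvalidParameterError("GSI has no starting date")
    return replace(params, t0=t0)
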