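"""Least-RMSE calibration by simulated annealing, plus validation metrics.

The calibration objective is the root-mean-square error between predicted
and observed leaf-unfolding days over the calibration years; years in
which a model never reaches its thresholds contribute a fixed penalty
error (``penalty_days``, default 400) so the objective stays finite and
pushes the search back towards parameter regions that produce dates.

Models are fitted on odd-numbered calendar years and validated on the
held-out even-numbered years (:func:`split_odd_even`). Goodness of fit is
summarised by RMSE, the squared Pearson correlation R^2, and the
regression F statistic F = R^2 (n-2) / (1 - R^2) with (1, n-2) degrees of
freedom.

The annealer is a plain Metropolis scheme on the box-bounded parameter
space: uniform perturbations of every free parameter, acceptance
probability min(1, exp(-delta/T)), geometric cooling, best-ever result
retained. An exhaustive grid search (:func:`fit_grid_oracle`) is provided
as an independent check for problems with at most three free parameters.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    CoverageError,
    DataValidationError,
    DegenerateInputError,
    InvalidParameterError,
)
from .models import (
    MODEL_NAMES,
    AMParams,
    GSIParams,
    PMParams,
    SMParams,
    StartDateSpec,
    SWParams,
    TPParams,
    YearContext,
    build_year_context,
    predict_from_context,
)
from .weather import LeafingObservation, StationSeries

__all__ = [
    "Metrics",
    "FitResult",
    "ParamSpec",
    "ParameterSpace",
    "AnnealConfig",
    "FitProblem",
    "rmse",
    "r_squared",
    "f_statistic",
    "split_odd_even",
    "objective",
    "fit_simulated_annealing",
    "fit_grid_oracle",
    "validate",
    "default_space",
    "make_params",
]

DEFAULT_PENALTY_DAYS = 400.0

# last admissible parameterized start date: Jun 30 of the leafing year,
# expressed as a day offset from Sep 1 of the previous year
_T0_OFFSET_MAX = 302


# ---------------------------------------------------------------------------
# metrics


def rmse(predicted, observed) -> float:
    """Root-mean-square error in days."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise DataValidationError(
            f"predicted/observed must be equal-length non-empty vectors, "
            f"got {p.shape} and {o.shape}"
        )
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(predicted, observed) -> float:
    """Squared Pearson correlation between predictions and observations."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise DataValidationError("r_squared needs equal-length vectors of length >= 3")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise DegenerateInputError("r_squared undefined for a constant vector")
    r = np.corrcoef(p, o)[0, 1]
    return float(r * r)


def f_statistic(r2: float, n: int) -> float:
    """Regression F statistic R^2 (n-2) / (1 - R^2), df (1, n-2)."""
    if not 0.0 <= r2 <= 1.0:
        raise DataValidationError(f"r2 must be in [0, 1], got {r2}")
    if n < 3:
        raise DataValidationError(f"need n >= 3, got {n}")
    if r2 == 1.0:
        raise DegenerateInputError("F statistic infinite at r2 = 1")
    return float(r2 * (n - 2) / (1.0 - r2))


@dataclass(frozen=True)
class Metrics:
    """RMSE (days), R^2, F and sample size for one set of predictions.

    ``r2`` and ``f_stat`` are NaN when undefined (fewer than three years,
    or a constant prediction vector — e.g. all-penalty substitutions).
    """

    rmse: float
    r2: float
    f_stat: float
    n: int

    @classmethod
    def from_predictions(cls, predicted, observed) -> "Metrics":
        e = rmse(predicted, observed)
        try:
            r2 = r_squared(predicted, observed)
        except (DataValidationError, DegenerateInputError):
            r2 = float("nan")
        try:
            f = f_statistic(r2, len(observed)) if not math.isnan(r2) else float("nan")
        except DegenerateInputError:  # r2 == 1 exactly
            f = float("inf")
        return cls(rmse=e, r2=r2, f_stat=f, n=len(observed))


def split_odd_even(
    observations: list[LeafingObservation],
) -> tuple[list[LeafingObservation], list[LeafingObservation]]:
    """Partition observations into (odd-year calibration, even-year validation)."""
    odd = [o for o in observations if o.year % 2 == 1]
    even = [o for o in observations if o.year % 2 == 0]
    return odd, even


# ---------------------------------------------------------------------------
# parameter space


@dataclass(frozen=True)
class ParamSpec:
    """One searchable parameter: box bounds, optionally pinned to a value."""

    name: str
    lower: float
    upper: float
    fixed: float | None = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidParameterError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )
        if self.fixed is not None and not self.lower <= self.fixed <= self.upper:
            raise InvalidParameterError(
                f"{self.name}: fixed value {self.fixed} outside [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered collection of ParamSpec defining the search box."""

    specs: tuple[ParamSpec, ...]

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise InvalidParameterError(f"duplicate parameter names in {names}")

    @property
    def free(self) -> tuple[ParamSpec, ...]:
        return tuple(s for s in self.specs if s.fixed is None)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.free)

    def values_from_vector(self, x: np.ndarray) -> dict[str, float]:
        values = {s.name: s.fixed for s in self.specs if s.fixed is not None}
        for s, v in zip(self.free, x):
            values[s.name] = float(v)
        return values

    def fix(self, **pins: float) -> "ParameterSpace":
        """Copy of the space with the named parameters pinned."""
        specs = []
        for s in self.specs:
            if s.name in pins:
                specs.append(ParamSpec(s.name, s.lower, s.upper, fixed=pins[s.name]))
            else:
                specs.append(s)
        unknown = set(pins) - {s.name for s in self.specs}
        if unknown:
            raise InvalidParameterError(f"unknown parameters {sorted(unknown)}")
        return ParameterSpace(tuple(specs))


def default_space(model: str, start_mode: str = "fixed") -> ParameterSpace:
    """Default search box per model.

    ``start_mode`` — "fixed" keeps the conventional starting date (Jan 1
    for SW/TP, Sep 1 of the previous year for SM/PM/AM); "parameterized"
    searches it as a day offset from Sep 1 of the previous year. For
    SM/PM, "fixed" additionally pins the chilling-bounds/sigmoid constants
    to the standard European values while "parameterized" frees them all.
    GSI searches only the leafing threshold.
    """
    if model not in MODEL_NAMES:
        raise DataValidationError(f"unknown model {model!r}; choose from {MODEL_NAMES}")
    if start_mode not in ("fixed", "parameterized"):
        raise DataValidationError(f"start_mode must be fixed|parameterized, got {start_mode!r}")
    free_t0 = start_mode == "parameterized"

    def t0_spec(fixed_offset: int) -> ParamSpec:
        return ParamSpec("t0_offset", 0, _T0_OFFSET_MAX,
                         fixed=None if free_t0 else fixed_offset)

    jan1_offset = 122  # Sep 1 -> Jan 1 of a non-leap following year
    sep1_offset = 0
    if model == "SW":
        return ParameterSpace((
            t0_spec(jan1_offset),
            ParamSpec("T_b", 0.0, 15.0),
            ParamSpec("F_star", 0.0, 1000.0),
        ))
    if model == "TP":
        return ParameterSpace((
            t0_spec(jan1_offset),
            ParamSpec("T_b", 0.0, 15.0),
            ParamSpec("F_star", 0.0, 1000.0),
            ParamSpec("k1", 0.0, 1.0),
            ParamSpec("k2", 0.0, 1.0),
            ParamSpec("P_crit", 0.0, 60.0),
        ))
    if model == "AM":
        return ParameterSpace((
            t0_spec(sep1_offset),
            ParamSpec("T_b", 0.0, 15.0),
            ParamSpec("C_star", 0.0, 100.0),
            ParamSpec("a", 1.0, 1000.0),
            ParamSpec("b", -0.2, 0.2),
        ))
    if model == "SM":
        fixed = not free_t0
        return ParameterSpace((
            t0_spec(sep1_offset),
            ParamSpec("T_b", 0.0, 15.0),
            ParamSpec("C_star", 0.0, 100.0),
            ParamSpec("F_star", 0.0, 1000.0),
            ParamSpec("T_o", -3.0, 10.0),
            ParamSpec("T_low", -10.0, 5.0, fixed=-3.4 if fixed else None),
            ParamSpec("T_high", 5.0, 20.0, fixed=10.4 if fixed else None),
            ParamSpec("va", 1.0, 70.0, fixed=28.4 if fixed else None),
            ParamSpec("vb", -0.9, -0.001, fixed=-0.185 if fixed else None),
            ParamSpec("vc", -60.0, 0.0, fixed=-18.4 if fixed else None),
        ))
    if model == "PM":
        fixed = not free_t0
        return ParameterSpace((
            t0_spec(sep1_offset),
            ParamSpec("C_star", 0.0, 100.0),
            ParamSpec("F_star", 0.0, 1000.0),
            ParamSpec("K_m", 0.0, 1.0),
            ParamSpec("T_o", -3.0, 10.0),
            ParamSpec("T_low", -10.0, 5.0, fixed=-3.4 if fixed else None),
            ParamSpec("T_high", 5.0, 20.0, fixed=10.4 if fixed else None),
            ParamSpec("va", 1.0, 70.0, fixed=28.4 if fixed else None),
            ParamSpec("vb", -0.9, -0.001, fixed=-0.185 if fixed else None),
            ParamSpec("vc", -60.0, 0.0, fixed=-18.4 if fixed else None),
        ))
    # GSI: only the leafing threshold is searched by default
    return ParameterSpace((
        ParamSpec("threshold", 0.01, 1.0),
    ))


def _start_spec(model: str, values: dict[str, float]) -> StartDateSpec:
    offset = values.get("t0_offset")
    if offset is None:
        return StartDateSpec.jan1() if model in ("SW", "TP") else StartDateSpec.sep1_prev()
    return StartDateSpec.from_offset(int(round(offset)))


def make_params(model: str, values: dict[str, float]):
    """Build the parameter object for ``model`` from a name->value dict.

    Raises :class:`InvalidParameterError` for inadmissible combinations
    (e.g. a chilling optimum outside its bounds); the objective maps
    those onto the penalty value rather than aborting the search.
    """
    if model == "GSI":
        fields = {k: v for k, v in values.items() if k != "t0_offset"}
        if "window" in fields:
            fields["window"] = int(round(fields["window"]))
        return GSIParams(**fields)
    t0 = _start_spec(model, values)
    fields = {k: v for k, v in values.items() if k != "t0_offset"}
    cls = {"SW": SWParams, "TP": TPParams, "SM": SMParams, "PM": PMParams, "AM": AMParams}[model]
    return cls(t0=t0, **fields)


# ---------------------------------------------------------------------------
# objective


class FitProblem:
    """Caches per-year weather contexts for fast repeated objective calls."""

    def __init__(
        self,
        model: str,
        series: StationSeries,
        observations: list[LeafingObservation],
        penalty_days: float = DEFAULT_PENALTY_DAYS,
    ):
        if model not in MODEL_NAMES:
            raise DataValidationError(f"unknown model {model!r}")
        if not observations:
            raise DataValidationError("empty observation set")
        self.model = model
        self.penalty_days = float(penalty_days)
        self.observed = np.array([o.leafing_doy for o in observations], dtype=float)
        self.years = [o.year for o in observations]
        missing = [o.year for o in observations
                   if not series.covers(_min_cover(model, o.year), _max_cover(o.year))]
        if missing:
            raise CoverageError(f"weather does not cover observation years {missing}")
        self.contexts: list[YearContext] = [build_year_context(series, y) for y in self.years]

    def predictions(self, values: dict[str, float]) -> np.ndarray:
        """Predicted DOY per observation year, penalty-substituted."""
        params = make_params(self.model, values)
        out = np.empty(len(self.contexts))
        for i, ctx in enumerate(self.contexts):
            pred = predict_from_context(ctx, params)
            if pred.leafing_doy is None:
                out[i] = self.observed[i] + self.penalty_days
            else:
                out[i] = pred.leafing_doy
        return out

    def objective(self, values: dict[str, float]) -> float:
        # inadmissible parameter combinations (ordering constraints, or a
        # proposed start date before the available window) are scored with
        # the penalty instead of aborting the stochastic search
        try:
            return rmse(self.predictions(values), self.observed)
        except (InvalidParameterError, CoverageError):
            return self.penalty_days


def _min_cover(model: str, year: int) -> dt.date:
    if model in ("SM", "PM", "AM"):
        return dt.date(year - 1, 9, 1)
    if model == "TP":
        return dt.date(year - 1, 1, 1)
    return dt.date(year, 1, 1)


def _max_cover(year: int) -> dt.date:
    return dt.date(year, 12, 31)


def objective(
    params_values: dict[str, float],
    model: str,
    series: StationSeries,
    observations: list[LeafingObservation],
    penalty_days: float = DEFAULT_PENALTY_DAYS,
) -> float:
    """RMSE of ``model`` with the given parameter values over the observations."""
    return FitProblem(model, series, observations, penalty_days).objective(params_values)


# ---------------------------------------------------------------------------
# simulated annealing


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule.

    ``initial_temp=None`` auto-calibrates the starting temperature from 50
    warm-up proposals so roughly 80% of initial uphill moves would be
    accepted. Cooling is geometric per epoch. ``seed`` is mandatory.
    """

    seed: int
    initial_temp: float | None = None
    cooling: float = 0.9
    steps_per_epoch: int = 200
    epochs: int = 50
    proposal_scale: float = 0.1
    penalty_days: float = DEFAULT_PENALTY_DAYS

    def __post_init__(self):
        if not 0.0 < self.cooling < 1.0:
            raise InvalidParameterError(f"cooling must be in (0, 1), got {self.cooling}")
        if self.penalty_days < 365:
            raise InvalidParameterError(
                f"penalty_days must be >= 365 (larger than any real DOY error), "
                f"got {self.penalty_days}"
            )


@dataclass(frozen=True)
class FitResult:
    """Best parameters found plus calibration (and optional validation) metrics."""

    model: str
    values: dict[str, float]
    params: object
    calibration: Metrics
    validation: Metrics | None
    trace: tuple[float, ...]
    seed: int | None
    n_evaluations: int = 0


def _metrics_for(problem: FitProblem, values: dict[str, float]) -> Metrics:
    return Metrics.from_predictions(problem.predictions(values), problem.observed)


def fit_simulated_annealing(
    model: str,
    series: StationSeries,
    calibration: list[LeafingObservation],
    space: ParameterSpace | None = None,
    cfg: AnnealConfig | None = None,
) -> FitResult:
    """Calibrate ``model`` on the given years by least-RMSE annealing.

    Deterministic for a fixed config seed; the per-epoch best-objective
    trace is non-increasing by construction.
    """
    if cfg is None:
        raise DataValidationError("an AnnealConfig with an explicit seed is required")
    if not calibration:
        raise DataValidationError("calibration set is empty")
    if space is None:
        space = default_space(model)
    problem = FitProblem(model, series, calibration, cfg.penalty_days)
    free = space.free
    n_eval = 0

    if not free:
        values = space.values_from_vector(np.empty(0))
        cal = _metrics_for(problem, values)
        return FitResult(model, values, make_params(model, values), cal, None,
                         trace=(cal.rmse,), seed=cfg.seed, n_evaluations=1)

    rng = np.random.default_rng(cfg.seed)
    lo = np.array([s.lower for s in free])
    hi = np.array([s.upper for s in free])
    width = hi - lo

    def f(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return problem.objective(space.values_from_vector(x))

    x = lo + rng.random(len(free)) * width
    fx = f(x)
    best_x, best_f = x.copy(), fx

    temp = cfg.initial_temp
    if temp is None:
        # warm-up: size the temperature to the local uphill landscape
        ups = []
        for _ in range(50):
            xp = np.clip(x + rng.uniform(-1, 1, len(free)) * cfg.proposal_scale * width, lo, hi)
            d = f(xp) - fx
            if d > 0:
                ups.append(d)
        temp = (float(np.mean(ups)) / -math.log(0.8)) if ups else 1.0

    trace = []
    for _ in range(cfg.epochs):
        for _ in range(cfg.steps_per_epoch):
            xp = np.clip(x + rng.uniform(-1, 1, len(free)) * cfg.proposal_scale * width, lo, hi)
            fp = f(xp)
            d = fp - fx
            if d <= 0 or rng.random() < math.exp(-d / max(temp, 1e-12)):
                x, fx = xp, fp
                if fx < best_f:
                    best_x, best_f = x.copy(), fx
        trace.append(best_f)
        temp *= cfg.cooling

    values = space.values_from_vector(best_x)
    cal = _metrics_for(problem, values)
    return FitResult(model, values, make_params(model, values), cal, None,
                     trace=tuple(trace), seed=cfg.seed, n_evaluations=n_eval)


def fit_grid_oracle(
    model: str,
    series: StationSeries,
    calibration: list[LeafingObservation],
    space: ParameterSpace,
    resolution: int = 25,
    penalty_days: float = DEFAULT_PENALTY_DAYS,
) -> FitResult:
    """Exhaustive Cartesian-grid search over at most three free parameters.

    Ties are broken toward smaller parameter values in declaration order
    (the first grid point visited with the minimal objective wins).
    """
    free = space.free
    if len(free) > 3:
        raise DataValidationError(
            f"grid oracle limited to <= 3 free parameters, got {len(free)}"
        )
    if not calibration:
        raise DataValidationError("calibration set is empty")
    problem = FitProblem(model, series, calibration, penalty_days)
    axes = [np.linspace(s.lower, s.upper, resolution) for s in free]
    best_x, best_f = None, math.inf
    n_eval = 0
    if not free:
        grid_iter = [np.empty(0)]
    else:
        mesh = np.meshgrid(*axes, indexing="ij")
        grid_iter = np.stack([m.ravel() for m in mesh], axis=-1)
    for x in grid_iter:
        fv = problem.objective(space.values_from_vector(np.atleast_1d(x)))
        n_eval += 1
        if fv < best_f:
            best_x, best_f = np.atleast_1d(x).copy(), fv
    values = space.values_from_vector(best_x)
    cal = _metrics_for(problem, values)
    return FitResult(model, values, make_params(model, values), cal, None,
                     trace=(best_f,), seed=None, n_evaluations=n_eval)


def validate(
    model: str,
    values: dict[str, float],
    series: StationSeries,
    validation: list[LeafingObservation],
    penalty_days: float = DEFAULT_PENALTY_DAYS,
) -> Metrics:
    """Metrics on held-out years with the same penalty policy as calibration."""
    if not validation:
        raise DataValidationError("validation set is empty")
    problem = FitProblem(model, series, validation, penalty_days)
    return _metrics_for(problem, values)
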