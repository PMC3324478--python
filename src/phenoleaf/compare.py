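"""Side-by-side model comparison on one station/species.

Fits each requested model on odd-numbered years by simulated annealing,
validates on the held-out even-numbered years, and collects a table of
calibration and validation statistics (RMSE, R^2, F, sample sizes) plus
the fitted parameters. A failure in one model's fit is recorded in its
row without aborting the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math

import pandas as pd

from . import __version__
from .errors import PhenoleafError
from .fitting import AnnealConfig, default_space, fit_simulated_annealing, split_odd_even, validate
from .io import params_to_dict
from .weather import LeafingObservation, StationSeries

__all__ = ["ComparisonReport", "run_compare"]

_METRIC_COLUMNS = [
    "model", "status", "n_cal", "n_val",
    "cal_rmse", "cal_r2", "cal_f",
    "val_rmse", "val_r2", "val_f",
]


@dataclasses.dataclass(frozen=True)
class ComparisonReport:
    """Comparison rows plus the provenance needed to reproduce them."""

    rows: tuple[dict, ...]
    seed: int
    config_hash: str
    version: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: r.get(k) for k in _METRIC_COLUMNS} for r in self.rows],
            columns=_METRIC_COLUMNS,
        )

    def to_json(self) -> str:
        """Deterministic JSON (NaN rendered as null, keys in fixed order)."""
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "rows": [_denan(r) for r in self.rows],
        }
        return json.dumps(payload, indent=2, allow_nan=False) + "\n"

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def write_csv(self, path) -> None:
        frame = self.to_frame().copy()
        # human-readable rounding for the table; never fed back into computation
        for col in ("cal_rmse", "val_rmse"):
            frame[col] = frame[col].round(2)
        frame.to_csv(path, index=False)


def _denan(obj):
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {k: _denan(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_denan(v) for v in obj]
    return obj


def _config_hash(models, start_mode, cfg: AnnealConfig) -> str:
    blob = json.dumps(
        {"models": list(models), "start_mode": start_mode,
         "anneal": dataclasses.asdict(cfg)},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_compare(
    series: StationSeries,
    observations: list[LeafingObservation],
    models: list[str],
    cfg: AnnealConfig,
    start_mode: str = "fixed",
    species: str | None = None,
) -> ComparisonReport:
    """Odd-year fit / even-year validation for each model in ``models``.

    Per-model annealing seeds are derived deterministically from
    ``cfg.seed`` so adding a model does not change the others' results.
    """
    if not models:
        raise PhenoleafError("at least one model must be requested")
    if species is not None:
        observations = [o for o in observations if o.species == species]
    calibration, validation_set = split_odd_even(observations)
    rows = []
    for i, model in enumerate(models):
        row: dict = {"model": model, "n_cal": len(calibration), "n_val": len(validation_set)}
        try:
            model_cfg = dataclasses.replace(cfg, seed=(cfg.seed + 1009 * i) % 2**31)
            space = default_space(model, start_mode)
            fit = fit_simulated_annealing(model, series, calibration, space, model_cfg)
            row.update(
                status="ok",
                cal_rmse=fit.calibration.rmse,
                cal_r2=fit.calibration.r2,
                cal_f=fit.calibration.f_stat,
                params=params_to_dict(fit.params),
                values={k: float(v) for k, v in sorted(fit.values.items())},
                anneal_seed=model_cfg.seed,
            )
            if validation_set:
                val = validate(model, fit.values, series, validation_set, cfg.penalty_days)
                row.update(val_rmse=val.rmse, val_r2=val.r2, val_f=val.f_stat)
            else:
                row.update(val_rmse=float("nan"), val_r2=float("nan"), val_f=float("nan"))
        except PhenoleafError as exc:
            row.update(status=f"error: {exc}", cal_rmse=float("nan"), cal_r2=float("nan"),
                       cal_f=float("nan"), val_rmse=float("nan"), val_r2=float("nan"),
                       val_f=float("nan"))
        rows.append(row)
    return ComparisonReport(
        rows=tuple(rows),
        seed=cfg.seed,
        config_hash=_config_hash(models, start_mode, cfg),
        version=__version__,
    )
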