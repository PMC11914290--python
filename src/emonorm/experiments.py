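"""Experiment drivers: gamma sweep, per-error contour grids, trait sweep.

Each driver runs a grid of parameter points, with a configured number of
independent replicate simulations per point, and returns a tidy
:class:`~emonorm.metrics.SweepTable` (one row per point and norm). Per-run
seeds are derived deterministically from the master seed and the grid
coordinates through ``numpy.random.SeedSequence``, so sweeps are exactly
reproducible and identical under serial or parallel execution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evolution import run_simulation
from .metrics import SweepTable, aggregate_runs
from .model_core import (EBIS_EMOTION_STRING, IS_BASE_STRING, BaseNorm,
                         EmotionNorm, NormPolicy, Params)

__all__ = ["ExperimentConfig", "DEFAULT_GAMMA_GRID", "error_grid_for_z",
           "derive_run_seed", "run_replicates", "sweep_gamma",
           "sweep_error_contours", "sweep_traits", "eta_difference_grid"]

#: 0 .. 1 in steps of 0.1, plus 0.95 to resolve the cusp region near gamma=1.
DEFAULT_GAMMA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                      0.95, 1.0)

# stream tags keeping the three experiments on disjoint seed sequences
_TAG_GAMMA, _TAG_ERRORS, _TAG_TRAITS = 1, 2, 3
_ERROR_NAMES = ("epsilon", "alpha", "chi")


def error_grid_for_z(z: int) -> tuple[float, ...]:
    """The studied error magnitudes {1e-3/z, 1e-2/z, 1e-1/z, 1/z, 10/z}."""
    return tuple(10.0 ** k / z for k in range(-3, 2))


def derive_run_seed(master_seed: int, *coords: int) -> int:
    """Stable 31-bit per-run seed from the master seed and integer grid
    coordinates (experiment tag, norm id, grid indices, replicate)."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(c) for c in coords))
    return int(ss.generate_state(1)[0] >> 1)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment family.

    ``runs=None`` uses the production defaults: 300 replicates per point
    for the gamma and trait sweeps, 100 for the error contours.
    """
    params: Params = field(default_factory=Params)
    base_norm: str = IS_BASE_STRING
    emotion_norm: str = EBIS_EMOTION_STRING
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    error_grid: tuple[float, ...] | None = None
    held_error_level: float = 0.0
    runs: int | None = None
    out_dir: str | None = None
    master_seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if not self.gamma_grid:
            raise ValueError("gamma grid must be non-empty")
        if self.runs is not None and self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    @property
    def emotion_policy_label(self) -> str:
        if (self.base_norm.upper() == IS_BASE_STRING
                and self.emotion_norm.upper() == EBIS_EMOTION_STRING):
            return "EBIS"
        return f"{self.base_norm.upper()}+{self.emotion_norm.upper()}"

    @property
    def baseline_policy_label(self) -> str:
        return "IS" if self.base_norm.upper() == IS_BASE_STRING \
            else self.base_norm.upper()

    def emotion_policy(self, gamma: float) -> NormPolicy:
        return NormPolicy(BaseNorm.from_string(self.base_norm),
                          EmotionNorm.from_string(self.emotion_norm), gamma)

    def baseline_policy(self, gamma: float) -> NormPolicy:
        """The emotion-blind baseline: the base norm lifted to the 8-entry
        table, so gamma genuinely has no effect."""
        base = BaseNorm.from_string(self.base_norm)
        return NormPolicy(base, EmotionNorm.lift(base), gamma)

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = Params(**raw.pop("params", {}))
        for key in ("gamma_grid", "error_grid"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(params=params, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["params"] = {k: v for k, v in raw["params"].items()
                         if v is not None}
        for key in ("gamma_grid", "error_grid"):
            if raw[key] is not None:
                raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _run_one(params: Params, policy: NormPolicy, seed: int):
    return run_simulation(params, policy, seed=seed)


def run_replicates(params: Params, policy: NormPolicy, seeds,
                   workers: int = 1):
    """Independent replicate runs with the given per-run seeds; parallel
    execution preserves replicate order, so results match a serial run."""
    seeds = list(seeds)
    if workers == 1:
        return [_run_one(params, policy, s) for s in seeds]
    from joblib import Parallel, delayed
    return Parallel(n_jobs=workers)(
        delayed(_run_one)(params, policy, s) for s in seeds)


def _point_row(config: ExperimentConfig, params: Params, policy: NormPolicy,
               label: str, gamma: float, n_runs: int, tag: int, norm_id: int,
               *grid_idx: int) -> dict:
    seeds = [derive_run_seed(config.master_seed, tag, norm_id, *grid_idx, rep)
             for rep in range(n_runs)]
    trajs = run_replicates(params, policy, seeds, config.workers)
    row = {"norm": label, "gamma": gamma, "epsilon": params.epsilon,
           "alpha": params.alpha, "chi": params.chi, "z": params.z}
    row.update(aggregate_runs(trajs))
    return row


_PARAM_COLUMNS = ("error_type", "error_value", "norm", "gamma", "epsilon",
                  "alpha", "chi", "z")


def sweep_gamma(config: ExperimentConfig) -> SweepTable:
    """Cooperation index per (norm, gamma): the emotion-based policy against
    the emotion-blind baseline at every gamma in the grid."""
    n_runs = config.runs if config.runs is not None else 300
    rows = []
    for gi, gamma in enumerate(config.gamma_grid):
        for norm_id, (label, policy) in enumerate(
                ((config.emotion_policy_label, config.emotion_policy(gamma)),
                 (config.baseline_policy_label, config.baseline_policy(gamma)))):
            rows.append(_point_row(config, config.params, policy, label,
                                   gamma, n_runs, _TAG_GAMMA, norm_id, gi))
    table = SweepTable.from_rows(rows, _PARAM_COLUMNS)
    _maybe_write(config, table, "sweep_gamma.csv")
    return table


def sweep_error_contours(config: ExperimentConfig) -> SweepTable:
    """Three contour grids, one per error channel.

    In each grid the named error sweeps the magnitude grid while the other
    two are held at ``held_error_level`` (default 0: each error in
    isolation); every (gamma, error value) point is run under both the
    emotion-based policy and the baseline so their eta difference can be
    formed.
    """
    n_runs = config.runs if config.runs is not None else 100
    grid = config.error_grid or error_grid_for_z(config.params.z)
    held = config.held_error_level
    rows = []
    for ei, error_name in enumerate(_ERROR_NAMES):
        for vi, value in enumerate(grid):
            errors = {name: (value if name == error_name else held)
                      for name in _ERROR_NAMES}
            params = config.params.replace(**errors)
            for gi, gamma in enumerate(config.gamma_grid):
                for norm_id, (label, policy) in enumerate(
                        ((config.emotion_policy_label,
                          config.emotion_policy(gamma)),
                         (config.baseline_policy_label,
                          config.baseline_policy(gamma)))):
                    row = {"error_type": error_name, "error_value": value}
                    row.update(_point_row(config, params, policy, label,
                                          gamma, n_runs, _TAG_ERRORS,
                                          norm_id, ei, vi, gi))
                    rows.append(row)
    table = SweepTable.from_rows(rows, _PARAM_COLUMNS)
    _maybe_write(config, table, "sweep_errors.csv")
    return table


def sweep_traits(config: ExperimentConfig) -> SweepTable:
    """Time-averaged strategy, emotional-profile and reputation frequencies
    per gamma, under the emotion-based policy only."""
    n_runs = config.runs if config.runs is not None else 300
    rows = []
    for gi, gamma in enumerate(config.gamma_grid):
        rows.append(_point_row(config, config.params,
                               config.emotion_policy(gamma),
                               config.emotion_policy_label, gamma, n_runs,
                               _TAG_TRAITS, 0, gi))
    table = SweepTable.from_rows(rows, _PARAM_COLUMNS)
    _maybe_write(config, table, "sweep_traits.csv")
    return table


def eta_difference_grid(table: SweepTable, emotion_label: str = "EBIS",
                        baseline_label: str = "IS"):
    """Pivot a contour sweep into per-error-type (gamma x error value) grids
    of eta(emotion policy) - eta(baseline)."""
    df = table.data
    keys = ["error_type", "error_value", "gamma"]
    emo = df[df["norm"] == emotion_label].set_index(keys)["eta_mean"]
    base = df[df["norm"] == baseline_label].set_index(keys)["eta_mean"]
    diff = (emo - base).rename("eta_diff").reset_index()
    return {name: sub.pivot(index="gamma", columns="error_value",
                            values="eta_diff")
            for name, sub in diff.groupby("error_type")}


def _maybe_write(config: ExperimentConfig, table: SweepTable,
                 filename: str) -> None:
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / filename)
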