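"""Cooperation index and replicate-level statistics.

The cooperation index eta of a run is the fraction of potential donation
acts (two per game) that were realized cooperations, summed over the
post-burn-in generations. Replicate runs of one parameter point are
aggregated into a tidy sweep-table row with the sample (n-1) standard
deviation of eta and the mean time-averaged trait/reputation frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import Params, Strategy

__all__ = ["Trajectory", "SweepTable", "cooperation_index", "aggregate_runs",
           "FREQ_COLUMNS", "STAT_COLUMNS"]


class ZeroActsError(ValueError):
    """Raised when eta is requested over a window with no interaction acts."""


@dataclass
class Trajectory:
    """Per-generation records of one simulation run.

    Arrays are indexed by generation: ``coop_acts``/``total_acts`` count the
    realized cooperative and total potential-donation acts of all evaluation
    games in that generation; frequency arrays are end-of-generation
    snapshots (``strategy_freq`` has one column per :class:`Strategy` in
    enum order).
    """
    params: Params
    coop_acts: np.ndarray
    total_acts: np.ndarray
    strategy_freq: np.ndarray      # (generations, 4)
    coop_ep_freq: np.ndarray
    good_freq: np.ndarray
    seed: int | None = None

    @property
    def n_generations(self) -> int:
        return len(self.coop_acts)

    @property
    def eta(self) -> float:
        """Run-level cooperation index over post-burn-in generations."""
        return cooperation_index(self, self.params.burn_in)

    def time_averaged_frequencies(self, burn_in: int | None = None) -> dict:
        """Post-burn-in time averages of trait and reputation frequencies."""
        if burn_in is None:
            burn_in = self.params.burn_in
        sl = slice(burn_in, None)
        out = {f"freq_{s.name.lower()}": float(self.strategy_freq[sl, s].mean())
               for s in Strategy}
        out["freq_coopEP"] = float(self.coop_ep_freq[sl].mean())
        out["freq_good"] = float(self.good_freq[sl].mean())
        return out


def cooperation_index(traj: Trajectory, burn_in: int | None = None) -> float:
    """eta = (cooperative acts) / (total acts) summed over generations after
    ``burn_in`` (default: the trajectory's own params.burn_in)."""
    if burn_in is None:
        burn_in = traj.params.burn_in
    if not 0 <= burn_in < traj.n_generations:
        raise ValueError(
            f"burn_in must lie in [0, {traj.n_generations}), got {burn_in}")
    total = int(traj.total_acts[burn_in:].sum())
    if total == 0:
        raise ZeroActsError("no interaction acts after burn-in; eta undefined")
    return float(traj.coop_acts[burn_in:].sum()) / total


FREQ_COLUMNS = ["freq_allc", "freq_alld", "freq_disc", "freq_pdisc",
                "freq_coopEP", "freq_good"]
STAT_COLUMNS = ["eta_mean", "eta_sd", *FREQ_COLUMNS, "n_runs", "seed0"]

_ECHO_FIELDS = ("b", "c", "z", "mu", "beta", "epsilon", "alpha", "chi",
                "generations", "burn_in", "execution_error_mode",
                "fitness_aggregation")


def _echo(params: Params) -> tuple:
    return tuple(getattr(params, f) for f in _ECHO_FIELDS)


def aggregate_runs(trajs) -> dict:
    """Aggregate replicate trajectories of one parameter point.

    Returns a sweep-table row: mean and sample (n-1) standard deviation of
    the run-level eta, plus the across-run mean of each time-averaged
    frequency. All trajectories must share the same parameter echo (seeds
    excluded). A single run reports sd 0 with a warning.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    echo0 = _echo(trajs[0].params)
    for t in trajs[1:]:
        if _echo(t.params) != echo0:
            raise ValueError("trajectories were run with mixed parameters")
    etas = np.array([t.eta for t in trajs])
    if len(etas) == 1:
        warnings.warn("single run: eta_sd reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(etas.std(ddof=1))
    freqs = pd.DataFrame([t.time_averaged_frequencies() for t in trajs])
    row = {"eta_mean": float(etas.mean()), "eta_sd": sd}
    row.update({k: float(freqs[k].mean()) for k in freqs.columns})
    row["n_runs"] = len(trajs)
    row["seed0"] = trajs[0].seed
    return row


@dataclass
class SweepTable:
    """Tidy table of aggregated replicate results for a parameter grid."""
    data: pd.DataFrame

    def to_csv(self, path) -> None:
        """Write with a stable column order and float format (so identical
        sweeps produce byte-identical files)."""
        self.data.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "SweepTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_rows(cls, rows, param_columns) -> "SweepTable":
        df = pd.DataFrame(list(rows))
        cols = [c for c in (*param_columns, *STAT_COLUMNS) if c in df.columns]
        extra = [c for c in df.columns if c not in cols]
        return cls(df[cols + extra])
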