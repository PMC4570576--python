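"""Exact stochastic simulation (Gillespie) of the switch-modulated network.

The transcription hazard is time-inhomogeneous (piecewise constant), which
is handled by restarting the exponential clock at every switch time: a
candidate waiting time that would cross the next switch is discarded and
the simulation resumes at the switch with updated hazards.  By the
memoryless property of the exponential this is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import CellParams

__all__ = ["ExactTrajectory", "simulate_exact", "sample_at_times",
           "simulate_on_grid", "pointwise_envelope"]


@dataclass(frozen=True)
class ExactTrajectory:
    """A complete reaction path: event times, reaction types (1..4) and the
    post-event states.  `x0` is the state at time 0."""

    times: np.ndarray
    types: np.ndarray
    states: np.ndarray  # (n_events, 2) integer states after each event
    x0: tuple
    horizon: float

    @property
    def n_events(self) -> int:
        return self.times.size


def simulate_exact(params: CellParams, horizon: float | None = None,
                   seed: int = 0) -> ExactTrajectory:
    """One exact sample path of the Markov jump process."""
    fn = params.switch_fn
    if horizon is None:
        horizon = fn.horizon
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if horizon > fn.horizon:
        raise ValueError("horizon exceeds the switch function's domain")
    ts, tys, Ms, Ps = _kernels.ssa_events(
        float(horizon), fn.times, fn.rates, params.delta_m, params.delta_p,
        params.alpha, int(round(params.M0)), int(round(params.P0)),
        np.uint32(seed))
    states = np.column_stack((Ms, Ps))
    return ExactTrajectory(ts, tys, states,
                           (int(round(params.M0)), int(round(params.P0))),
                           float(horizon))


def sample_at_times(traj: ExactTrajectory, grid) -> np.ndarray:
    """Right-continuous step interpolation of a trajectory on `grid`.

    Returns an (len(grid), 2) integer array of (M, P) states.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size and grid.max() > traj.horizon + 1e-12:
        raise ValueError("grid point beyond simulation horizon")
    if grid.size and grid.min() < 0:
        raise ValueError("grid point before time 0")
    idx = np.searchsorted(traj.times, grid, side="right")
    out = np.empty((grid.size, 2), dtype=np.int64)
    for i, j in enumerate(idx):
        out[i] = traj.x0 if j == 0 else traj.states[j - 1]
    return out


def simulate_on_grid(params: CellParams, grid, seed: int = 0) -> np.ndarray:
    """Exact simulation recording only the states on `grid` (fast path for
    Monte-Carlo ensembles)."""
    fn = params.switch_fn
    grid = np.asarray(grid, dtype=float)
    Mg, Pg = _kernels.ssa_grid(grid, fn.times, fn.rates, params.delta_m,
                               params.delta_p, params.alpha,
                               int(round(params.M0)), int(round(params.P0)),
                               np.uint32(seed))
    return np.column_stack((Mg, Pg))


def simulate_ensemble(params: CellParams, grid, n_paths: int,
                      seed: int = 0) -> np.ndarray:
    """(n_paths, len(grid), 2) array of exact grid-sampled paths, one
    counter-derived seed per path."""
    grid = np.asarray(grid, dtype=float)
    out = np.empty((n_paths, grid.size, 2), dtype=np.int64)
    for r in range(n_paths):
        out[r] = simulate_on_grid(params, grid, seed=(seed + r) % (2**31 - 1))
    return out


def pointwise_envelope(paths: np.ndarray, level: float = 0.95):
    """Per-time empirical quantile envelope of an ensemble of paths.

    `paths` has shape (n_paths, n_times) or (n_paths, n_times, n_species).
    Returns (lower, upper) arrays of shape (n_times,) or
    (n_times, n_species) at quantiles (1-level)/2 and 1-(1-level)/2.
    """
    paths = np.asarray(paths, dtype=float)
    if paths.ndim < 2 or paths.shape[0] < 2:
        raise ValueError("need at least two paths on a common grid")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    lo = (1 - level) / 2
    lower = np.quantile(paths, lo, axis=0)
    upper = np.quantile(paths, 1 - lo, axis=0)
    return lower, upper
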