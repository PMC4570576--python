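"""Linear noise approximation for the gene network.

The LNA writes X(t) = phi(t) + Omega^{-1/2} xi(t) with phi the macroscopic
ODE solution and xi a linear Gaussian SDE; we work in absolute molecule
numbers (Omega = 1).  Because all hazards are affine in the state, the
Jacobian J = [[-delta_m, 0], [alpha, -delta_p]] is constant, the
fluctuation mean propagates as exp(J tau) and the covariance is the
integral of exp(J(tau-s)) B B' exp(J'(tau-s)) with
B B' = S diag(h(phi(s))) S'.  Both are evaluated exactly per constant-beta
segment by embedding (phi, Sigma) in one linear ODE system and taking a
single matrix exponential (see txswitch._kernels).

For this affine-hazard network the LNA first and second conditional
moments coincide with those of the exact jump process; the Gaussian shape
is the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import CellParams

__all__ = ["LNAMoments", "ode_segment", "macroscopic_path", "lna_transition",
           "grid_moments", "simulate_lna_path", "jacobian"]


@dataclass(frozen=True)
class LNAMoments:
    """Gaussian transition law of the LNA over one interval."""

    mean: np.ndarray        # (2,)
    cov: np.ndarray         # (2,2)
    phi_start: np.ndarray   # macroscopic state at the interval start
    phi_end: np.ndarray


def jacobian(params: CellParams, scaled: bool = False) -> np.ndarray:
    """Drift Jacobian; with `scaled` the protein row is on the P~ = kappa*P
    scale (translation rate alpha~ = kappa*alpha)."""
    a = params.alpha_tilde if scaled else params.alpha
    return np.array([[-params.delta_m, 0.0], [a, -params.delta_p]])


def ode_segment(phi0, beta: float, params: CellParams, tau: float):
    """Closed-form macroscopic ODE solution over a constant-beta segment.

    phi_M(tau) = beta/dm + (phi_M(0) - beta/dm) e^{-dm tau} and phi_P by
    the matching two-exponential convolution; the repeated-eigenvalue limit
    is used when |dm - dp| < 1e-8.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    dm, dp, a = params.delta_m, params.delta_p, params.alpha
    m0, p0 = float(phi0[0]), float(phi0[1])
    em = np.exp(-dm * tau)
    ep = np.exp(-dp * tau)
    mbar = beta / dm
    m = mbar + (m0 - mbar) * em
    pbar = a * beta / (dm * dp)
    if abs(dm - dp) > 1e-8:
        p = (pbar + (p0 - pbar) * ep
             + a * (m0 - mbar) * (em - ep) / (dp - dm))
    else:
        p = pbar + (p0 - pbar) * ep + a * (m0 - mbar) * tau * em
    return np.array([m, p])


def macroscopic_path(params: CellParams, grid, scaled: bool = False):
    """Macroscopic ODE solution on `grid` from (M0, P0) (or (M0, P~0))."""
    grid = np.asarray(grid, dtype=float)
    fn = params.switch_fn
    at = params.alpha_tilde if scaled else params.alpha
    p0 = params.P0_tilde if scaled else params.P0
    kap = params.kappa if scaled else 1.0
    phi, _, _ = _kernels.lna_grid_moments(grid, fn.times, fn.rates,
                                          params.delta_m, params.delta_p,
                                          at, kap, float(params.M0),
                                          float(p0))
    return phi


def lna_transition(x, t: float, tau: float, params: CellParams,
                   scaled: bool = False) -> LNAMoments:
    """Gaussian LNA transition law of X(t+tau) given X(t) = x.

    The macroscopic path is run from the cell's initial condition; the
    covariance accumulates piecewise across any switch times in (t, t+tau).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("state must be >= 0")
    fn = params.switch_fn
    at = params.alpha_tilde if scaled else params.alpha
    p0 = params.P0_tilde if scaled else params.P0
    kap = params.kappa if scaled else 1.0
    grid = np.array([0.0, t, t + tau]) if t > 0 else np.array([0.0, tau])
    phi, F, Q = _kernels.lna_grid_moments(grid, fn.times, fn.rates,
                                          params.delta_m, params.delta_p,
                                          at, kap, float(params.M0),
                                          float(p0))
    phi_s, phi_e = phi[-2], phi[-1]
    mean = phi_e + F[-1] @ (x - phi_s)
    return LNAMoments(mean=mean, cov=Q[-1].copy(), phi_start=phi_s,
                      phi_end=phi_e)


def grid_moments(params: CellParams, grid, scaled: bool = False):
    """(phi, F, Q) arrays for all consecutive intervals of `grid`; the
    building blocks of the Kalman filter and of LNA path simulation."""
    grid = np.asarray(grid, dtype=float)
    fn = params.switch_fn
    at = params.alpha_tilde if scaled else params.alpha
    p0 = params.P0_tilde if scaled else params.P0
    kap = params.kappa if scaled else 1.0
    return _kernels.lna_grid_moments(grid, fn.times, fn.rates,
                                     params.delta_m, params.delta_p,
                                     at, kap, float(params.M0), float(p0))


def simulate_lna_path(params: CellParams, grid, seed: int = 0,
                      n_paths: int = 1, scaled: bool = False) -> np.ndarray:
    """Sequential draws from the LNA transition densities on `grid`.

    Returns (n_paths, len(grid), 2).  Values may go negative at low
    molecule numbers; this is the documented Gaussian artefact of the LNA.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    phi, F, Q = grid_moments(params, grid, scaled=scaled)
    T = grid.size - 1
    p0 = params.P0_tilde if scaled else params.P0
    x = np.tile(np.array([params.M0, p0], dtype=float), (n_paths, 1))
    out = np.empty((n_paths, T + 1, 2))
    out[:, 0] = x
    for i in range(T):
        mean = phi[i + 1] + (x - phi[i]) @ F[i].T
        # cholesky of 2x2 (Q may be singular when hazards vanish)
        q = Q[i]
        l00 = np.sqrt(max(q[0, 0], 0.0))
        l10 = q[0, 1] / l00 if l00 > 0 else 0.0
        l11 = np.sqrt(max(q[1, 1] - l10 * l10, 0.0))
        z = rng.standard_normal((n_paths, 2))
        x = mean + np.column_stack((l00 * z[:, 0],
                                    l10 * z[:, 0] + l11 * z[:, 1]))
        out[:, i + 1] = x
    return out
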