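"""Conditional sequential Monte Carlo (particle Gibbs) for the BDA.

The latent path (M_{1:T}, P~_{1:T}) is sampled conditionally on the
observations and parameters by an SMC sweep in which one particle is
pinned to the previous (reference) path; the returned path is drawn by
ancestral tracing with probability proportional to the final weights.
This kernel leaves the exact conditional f(x | y, theta) invariant.

Proposals: the mRNA component is proposed from its BDA truncated-normal
transition (bootstrap, weight contribution 1); the P~ component from the
Gaussian-conjugate combination of its transition with the N(y_t; P~, s^2)
observation density, truncated at zero.  The resulting incremental weight
is analytic and does not depend on the sampled value.  Resampling is
systematic, every step, without ancestor sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import CellParams, TimeSeries

__all__ = ["LatentPath", "ParticleSet", "csmc_sweep",
           "csmc_sweep_reference", "smc_loglik", "bda_path_loglik"]


@dataclass(frozen=True)
class LatentPath:
    """Latent states on the observation grid at times t_1..t_T (the state
    at t_0 is the parameter (M0, P~0))."""

    M: np.ndarray
    P: np.ndarray  # on the P~ = kappa*P scale

    def __post_init__(self):
        if self.M.shape != self.P.shape:
            raise ValueError("component length mismatch")


@dataclass(frozen=True)
class ParticleSet:
    """The particle system of one SMC sweep: per-time states, normalized
    importance weights and ancestor indices.  In the conditional sweep
    particle 0 is the reference slot and survives every resampling."""

    M: np.ndarray          # (T, N_p)
    P: np.ndarray          # (T, N_p)
    weights: np.ndarray    # (T, N_p), each row sums to 1
    ancestors: np.ndarray  # (T, N_p) integer indices
    reference_slot: int = 0


class ParticleCollapse(RuntimeError):
    """All particle weights vanished; retry with more particles."""


def _args(y: TimeSeries, params: CellParams):
    fn = params.switch_fn
    return (y.values, y.times, fn.times, fn.rates, params.delta_m,
            params.delta_p, params.alpha_tilde, params.kappa,
            params.sigma_eps, float(params.M0), float(params.P0_tilde))


def initial_path(y: TimeSeries, params: CellParams) -> LatentPath:
    """A crude but valid starting path: mRNA at the transition mean,
    P~ at the positive part of the data."""
    T = len(y) - 1
    pM, lam, _, _ = _kernels.bda_interval_consts(
        y.times, params.switch_fn.times, params.switch_fn.rates,
        params.delta_m, params.delta_p)
    M = np.empty(T)
    m = float(params.M0)
    for i in range(T):
        m = m * pM[i] + lam[i]
        M[i] = max(m, 1e-3)
    P = np.maximum(y.values[1:], 1e-3)
    return LatentPath(M=M, P=P)


def csmc_sweep(y: TimeSeries, params: CellParams, reference: LatentPath,
               n_particles: int = 100, seed: int = 0) -> LatentPath:
    """One conditional-SMC sweep; returns a fresh draw of the latent path."""
    if n_particles < 1:
        raise ValueError("need at least one particle")
    M, P, ll, _ = _kernels.csmc_core(*_args(y, params), reference.M,
                                     reference.P, n_particles,
                                     np.uint32(seed), True)
    if not np.isfinite(ll):
        raise ParticleCollapse("all particle weights vanished")
    return LatentPath(M=M, P=P)


def csmc_sweep_reference(y: TimeSeries, params: CellParams,
                         reference: LatentPath, n_particles: int = 100,
                         seed: int = 0):
    """Plain-Python conditional SMC, returning the drawn path and the
    full ParticleSet.  Mirrors the compiled kernel step for step (same
    proposals and weights, different random streams); kept as a readable
    reference and for particle-system diagnostics on small problems."""
    from scipy import special
    rng = np.random.default_rng(seed)
    p = params
    fn = p.switch_fn
    pM, lam, pP, fP = _kernels.bda_interval_consts(
        y.times, fn.times, fn.rates, p.delta_m, p.delta_p)
    at, kap, s2 = p.alpha_tilde, p.kappa, p.sigma_eps ** 2
    T = len(y) - 1
    Np = n_particles
    Mh = np.empty((T, Np))
    Ph = np.empty((T, Np))
    W = np.empty((T, Np))
    A = np.empty((T, Np), dtype=int)
    Mcur = np.full(Np, float(p.M0))
    Pcur = np.full(Np, float(p.P0_tilde))
    w = np.full(Np, 1.0 / Np)

    def tn_draw(mu, sd):
        a = special.ndtr(-mu / sd)
        u = rng.uniform(size=np.shape(mu))
        return mu + sd * special.ndtri(
            np.clip(a + u * (1 - a), 1e-16, 1 - 1e-16))

    for i in range(T):
        if i == 0:
            anc = np.arange(Np)
        else:
            u = rng.random()
            pos = (np.arange(Np) + u) / Np
            anc = np.searchsorted(np.cumsum(w), pos)
            anc[0] = 0
        A[i] = anc
        mprev = Mcur[anc]
        pprev = Pcur[anc]
        muM = mprev * pM[i] + lam[i]
        vM = np.maximum(mprev * pM[i] * (1 - pM[i]) + lam[i], 1e-12)
        muP = pprev * pP[i] + at * mprev * fP[i]
        vP = np.maximum(kap * (pprev * pP[i] * (1 - pP[i])
                               + at * mprev * fP[i]), 1e-12)
        vst = 1.0 / (1.0 / vP + 1.0 / s2)
        mst = vst * (muP / vP + y.values[i + 1] / s2)
        m = tn_draw(muM, np.sqrt(vM))
        pp_ = tn_draw(mst, np.sqrt(vst))
        m[0] = reference.M[i]
        pp_[0] = reference.P[i]
        logw = (-0.5 * np.log(2 * np.pi * (vP + s2))
                - 0.5 * (y.values[i + 1] - muP) ** 2 / (vP + s2)
                + special.log_ndtr(mst / np.sqrt(vst))
                - special.log_ndtr(muP / np.sqrt(vP)))
        w = np.exp(logw - logw.max())
        w /= w.sum()
        Mh[i] = m
        Ph[i] = pp_
        W[i] = w
        Mcur, Pcur = m, pp_
    j = rng.choice(Np, p=w)
    Mout = np.empty(T)
    Pout = np.empty(T)
    for i in range(T - 1, -1, -1):
        Mout[i] = Mh[i, j]
        Pout[i] = Ph[i, j]
        j = A[i, j]
    return LatentPath(M=Mout, P=Pout), ParticleSet(M=Mh, P=Ph, weights=W,
                                                   ancestors=A)


def smc_loglik(y: TimeSeries, params: CellParams, n_particles: int = 100,
               seed: int = 0, model: str = "bda") -> float:
    """Unconditional SMC estimate of the marginal log-likelihood.

    model="bda": the truncated-normal birth-death model (the sampler's
    target).  model="lna": bootstrap filter on the linear-Gaussian LNA
    model, for which the Kalman filter gives the exact value (used as a
    cross-check of SMC evidence unbiasedness).
    """
    if model == "bda":
        ref = initial_path(y, params)
        _, _, ll, _ = _kernels.csmc_core(*_args(y, params), ref.M, ref.P,
                                         n_particles, np.uint32(seed), False)
        if not np.isfinite(ll):
            import warnings
            warnings.warn("particle collapse: -inf evidence estimate")
        return float(ll)
    if model == "lna":
        from .lna import grid_moments
        phi, F, Q = grid_moments(params, y.times, scaled=True)
        return float(_kernels.smc_lna_loglik(
            y.values, phi, F, Q, params.sigma_eps, float(params.M0),
            float(params.P0_tilde), n_particles, np.uint32(seed)))
    raise ValueError(f"unknown model {model!r}")


def bda_path_loglik(path: LatentPath, y: TimeSeries,
                    params: CellParams) -> float:
    """Complete-data log density log f(x | theta) + log g(y | x, theta)
    of a latent path under the BDA; the parameter-update target of the
    Gibbs sampler."""
    return float(_kernels.bda_path_loglik(path.M, path.P, *_args(y, params)))
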