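"""Birth-death decomposition (BDD) and its truncated-normal approximation.

The joint transition of (M, P) factorizes as an exact immigration-death
law for mRNA and an immigration-death law for protein conditioned on the
mRNA value at the start of the interval (held constant across the
interval, the defining approximation of the decomposition):

    M(t+tau) | M(t)=m0  =  Binomial(m0, e^{-dm tau}) + Poisson(lam),
    lam = integral_t^{t+tau} beta(s) e^{-dm (t+tau-s)} ds,

and analogously for protein with immigration rate alpha * m0.  The mRNA
marginal is exact; the protein law is approximate.  The BDA replaces the
Poisson-binomial convolutions by moment-matched normal densities truncated
to the positive half line, which is what the particle Gibbs sampler works
with (latent states become continuous positive reals, so the kappa-scaled
P~ = kappa*P fits naturally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from . import _kernels
from .model import CellParams, SwitchFunction

__all__ = ["BDDTransition", "mrna_transition", "protein_transition",
           "TruncatedNormal", "truncnorm_approx", "bda_joint_logpdf",
           "bdd_pmf", "simulate_bdd_paths", "simulate_bda_paths"]

_SQRT2PI = np.sqrt(2 * np.pi)


@dataclass(frozen=True)
class BDDTransition:
    """One immigration-death transition: Binomial(n0, p) survivors plus
    Poisson(lam) immigrants, with n0 the (real-valued) start count."""

    n0: float
    p: float
    lam: float

    @property
    def mean(self) -> float:
        return self.n0 * self.p + self.lam

    @property
    def var(self) -> float:
        return self.n0 * self.p * (1.0 - self.p) + self.lam


def mrna_transition(m0: float, fn: SwitchFunction, delta_m: float,
                    t: float, tau: float) -> BDDTransition:
    """Exact mRNA transition law over (t, t+tau); the immigration mean is
    integrated exactly across any switch times inside the interval."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if m0 < 0:
        raise ValueError("m0 must be >= 0")
    lam = _kernels.lam_mrna(t, t + tau, fn.times, fn.rates, delta_m)
    return BDDTransition(n0=float(m0), p=float(np.exp(-delta_m * tau)),
                         lam=float(lam))


def protein_transition(p0: float, m_prev: float, alpha: float,
                       delta_p: float, tau: float,
                       kappa: float = 1.0) -> BDDTransition:
    """Protein transition with the interval-start mRNA count held fixed.

    With `kappa` != 1 the law is for P~ = kappa*P: the returned transition
    carries kappa-scaled moments (mean x kappa, variance x kappa^2), i.e.
    n0 and lam are expressed on the scaled axis.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if p0 < 0 or m_prev < 0:
        raise ValueError("states must be >= 0")
    p = float(np.exp(-delta_p * tau))
    lam = alpha * m_prev / delta_p * (1.0 - p) if delta_p > 0 \
        else alpha * m_prev * tau
    # on the scaled axis: survivors kappa*Binomial -> mean kappa*p0*p,
    # var kappa^2 p0 p(1-p); represented via scaled n0 and lam
    return _ScaledBDD(n0=float(p0), p=p, lam=float(lam), kappa=float(kappa))


@dataclass(frozen=True)
class _ScaledBDD(BDDTransition):
    kappa: float = 1.0

    @property
    def mean(self) -> float:
        return self.kappa * (self.n0 * self.p + self.lam)

    @property
    def var(self) -> float:
        return self.kappa ** 2 * (self.n0 * self.p * (1.0 - self.p) + self.lam)


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mu, var) truncated to (0, inf), correctly renormalized."""

    mu: float
    var: float

    @property
    def _alpha(self) -> float:
        return -self.mu / np.sqrt(self.var)

    def logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = np.sqrt(self.var)
        z = (x - self.mu) / sd
        out = -0.5 * z * z - np.log(sd * _SQRT2PI) \
            - special.log_ndtr(self.mu / sd)
        return np.where(x > 0, out, -np.inf)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def mean(self) -> float:
        a = self._alpha
        sd = np.sqrt(self.var)
        return self.mu + sd * stats.norm.pdf(a) / stats.norm.sf(a)

    def rvs(self, size=None, rng=None) -> np.ndarray:
        rng = np.random.default_rng(rng)
        u = rng.uniform(size=size)
        a = special.ndtr(self._alpha)
        return self.mu + np.sqrt(self.var) * special.ndtri(a + u * (1 - a))


def truncnorm_approx(transition: BDDTransition) -> TruncatedNormal:
    """Moment-matched positive-truncated normal density of a BDD
    transition (the BDA's working density)."""
    return TruncatedNormal(mu=transition.mean, var=transition.var)


def bda_joint_logpdf(state_new, state_old, params: CellParams, t: float,
                     tau: float) -> float:
    """Factorized BDA log transition density on the (M, P~) scale:
    log p(M'|M) + log p(P~'|P~, M), per the decomposition."""
    m1, p1 = float(state_new[0]), float(state_new[1])
    m0, p0 = float(state_old[0]), float(state_old[1])
    trm = mrna_transition(m0, params.switch_fn, params.delta_m, t, tau)
    trp = protein_transition(p0 / params.kappa, m0, params.alpha,
                             params.delta_p, tau, kappa=params.kappa)
    lm = truncnorm_approx(trm).logpdf(m1)
    lp = truncnorm_approx(trp).logpdf(p1)
    return float(lm + lp)


def bdd_pmf(transition: BDDTransition, n_max: int) -> np.ndarray:
    """Exact pmf of the Binomial-plus-Poisson convolution on {0..n_max}.

    Test oracle only; requires an integer start count.
    """
    n0 = int(round(transition.n0))
    binom = stats.binom.pmf(np.arange(n0 + 1), n0, transition.p)
    pois = stats.poisson.pmf(np.arange(n_max + 1), transition.lam)
    out = np.convolve(binom, pois)[:n_max + 1]
    return out


def _interval_consts(params: CellParams, grid):
    fn = params.switch_fn
    return _kernels.bda_interval_consts(np.asarray(grid, dtype=float),
                                        fn.times, fn.rates, params.delta_m,
                                        params.delta_p)


def simulate_bdd_paths(params: CellParams, grid, n_paths: int,
                       seed: int = 0) -> np.ndarray:
    """Ensemble of exact-BDD discrete paths on `grid` (integer counts),
    shape (n_paths, len(grid), 2)."""
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    pM, lam, pP, fP = _interval_consts(params, grid)
    T = grid.size - 1
    out = np.empty((n_paths, T + 1, 2), dtype=np.int64)
    M = np.full(n_paths, int(round(params.M0)), dtype=np.int64)
    P = np.full(n_paths, int(round(params.P0)), dtype=np.int64)
    out[:, 0, 0] = M
    out[:, 0, 1] = P
    a = params.alpha
    for i in range(T):
        lamP = a * M * fP[i]
        Mn = rng.binomial(M, pM[i]) + rng.poisson(lam[i], n_paths)
        P = rng.binomial(P, pP[i]) + rng.poisson(lamP)
        M = Mn
        out[:, i + 1, 0] = M
        out[:, i + 1, 1] = P
    return out


def simulate_bda_paths(params: CellParams, grid, n_paths: int,
                       seed: int = 0) -> np.ndarray:
    """Ensemble of BDA paths (positive-truncated normal transitions,
    continuous states) on the molecule scale, shape (n_paths, T+1, 2)."""
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    pM, lam, pP, fP = _interval_consts(params, grid)
    T = grid.size - 1
    out = np.empty((n_paths, T + 1, 2))
    M = np.full(n_paths, float(params.M0))
    P = np.full(n_paths, float(params.P0))
    out[:, 0, 0] = M
    out[:, 0, 1] = P
    a = params.alpha
    for i in range(T):
        muM = M * pM[i] + lam[i]
        vM = np.maximum(M * pM[i] * (1 - pM[i]) + lam[i], 1e-12)
        lamP = a * M * fP[i]
        muP = P * pP[i] + lamP
        vP = np.maximum(P * pP[i] * (1 - pP[i]) + lamP, 1e-12)
        M = _tn_rvs(muM, np.sqrt(vM), rng)
        P = _tn_rvs(muP, np.sqrt(vP), rng)
        out[:, i + 1, 0] = M
        out[:, i + 1, 1] = P
    return out


def _tn_rvs(mu, sd, rng):
    """Vectorized positive-truncated normal draws via inverse cdf."""
    a = special.ndtr(-mu / sd)
    u = rng.uniform(size=np.shape(mu))
    q = a + u * (1 - a)
    # guard against q -> 1 rounding
    q = np.clip(q, 1e-16, 1 - 1e-16)
    return mu + sd * special.ndtri(q)
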