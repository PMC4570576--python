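"""Posterior sampler for the stochastic switch model.

One Gibbs iteration updates, in order: the population hyper-parameters
(conjugate draws), then per cell a reversible-jump move on the switch
configuration (add / delete / move a switch), two adaptive random-walk
Metropolis-Hastings blocks on the log parameters, and -- when the
birth-death approximation (BDA) is the likelihood -- a particle Gibbs
(conditional SMC) refresh of the latent path.

Likelihoods: under the LNA the marginal likelihood is exact via the
Kalman filter; under the BDA the target is the joint posterior of
parameters and latent states and parameter moves use the complete-data
density of the current path.

Blocks follow the alpha-kappa reparameterization: block 1 is
log(beta_0..beta_k, delta_m, delta_p, M0), block 2 is
log(alpha~, kappa, sigma_eps, P~0).  Block-2 proposals use the full
adapted chain covariance; block 1 changes dimension with k, so its
proposal is diagonal with per-coordinate adapted scales (rates share one
pooled scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import bda_path_loglik as _bda_ll_core
from ._kernels import csmc_core, kalman_loglik_core
from .model import HyperParams, TimeSeries
from .priors import (PriorConfig, log_prior_k, log_prior_s,
                     mix_logpdf_arr, mix_sample, norm_logpdf)
from .smc import LatentPath, initial_path

__all__ = ["MCMCConfig", "ChainState", "PosteriorStore", "run_chain",
           "posterior_profile", "hyper_update"]


@dataclass
class MCMCConfig:
    method: str = "lna"            # "lna" | "bda"
    n_iter: int = 10000
    thin: int = 0                  # 0 -> auto (~4000 stored draws)
    n_particles: int = 100
    seed: int = 1
    kappa_mode: str = "free"       # "free" | "fixed"
    kappa_values: np.ndarray | None = None
    update_hypers: bool = True
    flat_likelihood: bool = False  # sample the prior (validation mode)
    adapt_start: int = 2000
    fixed_sd: float = 0.05         # proposal sd before adaptation kicks in


class CellState:
    """Mutable per-cell parameter state (all positive parameters on the
    log scale) plus the cached log-likelihood and BDA latent path."""

    __slots__ = ("s", "lb", "ldm", "ldp", "lat", "lkap", "lsig", "lM0",
                 "lP0", "ll", "path")

    def __init__(self, s, lb, ldm, ldp, lat, lkap, lsig, lM0, lP0):
        self.s = np.asarray(s, dtype=float)
        self.lb = np.asarray(lb, dtype=float)
        self.ldm = ldm
        self.ldp = ldp
        self.lat = lat
        self.lkap = lkap
        self.lsig = lsig
        self.lM0 = lM0
        self.lP0 = lP0
        self.ll = -np.inf
        self.path: LatentPath | None = None

    @property
    def k(self) -> int:
        return self.s.size


@dataclass
class ChainState:
    """Full sampler state: per-cell parameters, hyper-parameters and
    adaptation accumulators."""

    cells: list
    hyper: HyperParams
    priors: PriorConfig
    config: MCMCConfig
    data: list
    rng: np.random.Generator
    iteration: int = 0
    adapt: list = field(default_factory=list)
    accept: dict = field(default_factory=dict)


@dataclass
class PosteriorStore:
    """Thinned posterior draws.  `params` columns are PARAM_NAMES (log
    scale); switch configurations are ragged lists per draw."""

    method: str
    n_iter: int
    thin: int
    cell_ids: list
    k: list                 # per cell: int array (n_draws,)
    switch_times: list      # per cell: list of arrays
    log_rates: list         # per cell: list of arrays
    params: list            # per cell: (n_draws, 7) array
    hyper: np.ndarray
    accept: dict

    PARAM_NAMES = ("log_delta_m", "log_delta_p", "log_alpha_tilde",
                   "log_kappa", "log_sigma_eps", "log_M0", "log_P0_tilde")
    HYPER_NAMES = ("mu_alpha", "var_alpha", "mu_kappa", "var_kappa",
                   "mu_sigma", "var_sigma", "w_beta_1", "mu_beta_1",
                   "var_beta_1", "w_beta_2", "mu_beta_2", "var_beta_2")

    @property
    def n_draws(self) -> int:
        return self.k[0].size if self.k else 0

    def burn_slice(self, frac: float = 0.5) -> slice:
        return slice(int(self.n_draws * frac), None)


# ---------------------------------------------------------------------------
# likelihood dispatch
# ---------------------------------------------------------------------------

def _loglik(method, y: TimeSeries, cell: CellState, s=None, lb=None,
            scal=None):
    """Log-likelihood at (optionally proposed) parameter values.

    scal = (ldm, ldp, lat, lkap, lsig, lM0, lP0) overrides the scalars.
    """
    if s is None:
        s = cell.s
    if lb is None:
        lb = cell.lb
    if scal is None:
        scal = (cell.ldm, cell.ldp, cell.lat, cell.lkap, cell.lsig,
                cell.lM0, cell.lP0)
    ldm, ldp, lat, lkap, lsig, lM0, lP0 = scal
    args = (y.values, y.times, s, np.exp(lb), math.exp(ldm),
            math.exp(ldp), math.exp(lat), math.exp(lkap), math.exp(lsig),
            math.exp(lM0), math.exp(lP0))
    if method == "lna":
        return kalman_loglik_core(*args)
    return _bda_ll_core(cell.path.M, cell.path.P, *args)


def _scalar_prior(cell_scal, hyper: HyperParams, cfg: PriorConfig) -> float:
    ldm, ldp, lat, lkap, lsig, lM0, lP0 = cell_scal
    lp = norm_logpdf(ldm, cfg.mu_dm, cfg.sd_dm)
    lp += norm_logpdf(ldp, cfg.mu_dp, cfg.sd_dp)
    lp += norm_logpdf(lat - lkap, hyper.mu_alpha, math.sqrt(hyper.var_alpha))
    lp += norm_logpdf(lkap, hyper.mu_kappa, math.sqrt(hyper.var_kappa))
    lp += norm_logpdf(lsig, hyper.mu_sigma, math.sqrt(hyper.var_sigma))
    lp += norm_logpdf(lM0, cfg.mu_lM0, cfg.sd_lM0)
    lp += norm_logpdf(lP0, cfg.mu_lP0, cfg.sd_lP0)
    return lp


# ---------------------------------------------------------------------------
# adaptation accumulators
# ---------------------------------------------------------------------------

class _BlockAdapt:
    """Running mean / covariance of a fixed-dimension block (Welford),
    with a cached Cholesky factor of the scaled proposal covariance."""

    def __init__(self, dim: int):
        self.dim = dim
        self.n = 0
        self.mean = np.zeros(dim)
        self.M2 = np.zeros((dim, dim))
        self.chol = None
        self._since = 0

    def update(self, x: np.ndarray):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.M2 += np.outer(d, x - self.mean)
        self._since += 1

    def proposal_chol(self):
        if self.n < 10:
            return None
        if self.chol is None or self._since >= 25:
            cov = self.M2 / (self.n - 1)
            cov = (2.38 ** 2 / self.dim) * cov + 1e-6 * np.eye(self.dim)
            self.chol = np.linalg.cholesky(cov)
            self._since = 0
        return self.chol


class _DiagAdapt:
    """Per-coordinate running variances for the variable-dimension block:
    one pooled scale for all log rates plus one per fixed coordinate."""

    def __init__(self, n_fixed: int = 3):
        self.n = np.zeros(1 + n_fixed)
        self.mean = np.zeros(1 + n_fixed)
        self.M2 = np.zeros(1 + n_fixed)

    def update_one(self, j: int, x: float):
        self.n[j] += 1
        d = x - self.mean[j]
        self.mean[j] += d / self.n[j]
        self.M2[j] += d * (x - self.mean[j])

    def var(self, j: int) -> float:
        if self.n[j] < 10:
            return np.nan
        return self.M2[j] / (self.n[j] - 1)


# ---------------------------------------------------------------------------
# Gibbs sub-updates
# ---------------------------------------------------------------------------

def rj_update(state: ChainState, ci: int) -> bool:
    """One reversible-jump proposal (add/delete/move a switch) for cell ci.
    Returns acceptance."""
    cfg = state.priors
    cell = state.cells[ci]
    y = state.data[ci]
    rng = state.rng
    hyper = state.hyper
    T = cfg.horizon
    k = cell.k
    u = rng.random()
    if u < 1.0 / 3.0:  # add
        if k >= cfg.k_max:
            return False
        s_new = rng.uniform(0.0, T)
        j = int(np.searchsorted(cell.s, s_new))
        left = cell.s[j - 1] if j > 0 else 0.0
        right = cell.s[j] if j < k else T
        if s_new - left < cfg.min_sep or right - s_new < cfg.min_sep:
            return False
        lb_new = mix_sample(hyper, rng)
        if abs(lb_new) > cfg.log_bound:
            return False
        keep_left = rng.random() < 0.5
        s_prop = np.insert(cell.s, j, s_new)
        # old rate lb[j] covered [left, right); it stays on one side
        if keep_left:
            lb_prop = np.insert(cell.lb, j + 1, lb_new)
        else:
            lb_prop = np.insert(cell.lb, j, lb_new)
        ll_prop = _loglik(state.config.method, y, cell, s=s_prop, lb=lb_prop)
        if not np.isfinite(ll_prop):
            return False
        log_a = (ll_prop - cell.ll
                 + log_prior_k(k + 1, cfg) - log_prior_k(k, cfg)
                 + log_prior_s(k + 1, cfg) - log_prior_s(k, cfg)
                 + math.log(T) - math.log(k + 1))
        if math.log(rng.random() + 1e-300) < log_a:
            cell.s = s_prop
            cell.lb = lb_prop
            cell.ll = ll_prop
            return True
        return False
    if u < 2.0 / 3.0:  # delete
        if k == 0:
            return False
        j = int(rng.integers(k))
        keep_left = rng.random() < 0.5
        s_prop = np.delete(cell.s, j)
        # rates lb[j], lb[j+1] flank switch j; one survives
        if keep_left:
            removed = cell.lb[j + 1]
            lb_prop = np.delete(cell.lb, j + 1)
        else:
            removed = cell.lb[j]
            lb_prop = np.delete(cell.lb, j)
        ll_prop = _loglik(state.config.method, y, cell, s=s_prop, lb=lb_prop)
        if not np.isfinite(ll_prop):
            return False
        log_a = (ll_prop - cell.ll
                 + log_prior_k(k - 1, cfg) - log_prior_k(k, cfg)
                 + log_prior_s(k - 1, cfg) - log_prior_s(k, cfg)
                 + math.log(k) - math.log(T))
        if math.log(rng.random() + 1e-300) < log_a:
            cell.s = s_prop
            cell.lb = lb_prop
            cell.ll = ll_prop
            return True
        return False
    # move
    if k == 0:
        return False
    j = int(rng.integers(k))
    s_new = cell.s[j] + rng.normal(0.0, cfg.move_sd)
    left = cell.s[j - 1] if j > 0 else 0.0
    right = cell.s[j + 1] if j < k - 1 else T
    if s_new - left < cfg.min_sep or right - s_new < cfg.min_sep:
        return False
    s_prop = cell.s.copy()
    s_prop[j] = s_new
    ll_prop = _loglik(state.config.method, y, cell, s=s_prop)
    if not np.isfinite(ll_prop):
        return False
    if math.log(rng.random() + 1e-300) < ll_prop - cell.ll:
        cell.s = s_prop
        cell.ll = ll_prop
        return True
    return False


def mh_update_block(state: ChainState, ci: int, block_id: int) -> bool:
    """Adaptive random-walk MH on one log-parameter block of cell ci."""
    cfg = state.priors
    conf = state.config
    cell = state.cells[ci]
    y = state.data[ci]
    rng = state.rng
    hyper = state.hyper
    kap_free = conf.kappa_mode == "free"
    diag_adapt, blk_adapt = state.adapt[ci]

    if block_id == 1:
        nr = cell.lb.size
        x = np.concatenate((cell.lb, [cell.ldm, cell.ldp, cell.lM0]))
        d = x.size
        adapting = state.iteration >= conf.adapt_start and rng.random() > 0.05
        sd = np.full(d, conf.fixed_sd)
        if adapting:
            scale = 2.38 ** 2 / d
            vr = diag_adapt.var(0)
            if np.isfinite(vr):
                sd[:nr] = math.sqrt(scale * vr + 1e-6)
            for jj, name in enumerate((1, 2, 3)):
                vr = diag_adapt.var(name)
                if np.isfinite(vr):
                    sd[nr + jj] = math.sqrt(scale * vr + 1e-6)
        else:
            # tighter default steps for the tightly-constrained degradations
            sd[nr:nr + 2] = min(conf.fixed_sd, 0.04)
        xp = x + sd * rng.standard_normal(d)
        if np.abs(xp).max() > cfg.log_bound:
            return False
        lb_p = xp[:nr]
        scal_p = (xp[nr], xp[nr + 1], cell.lat, cell.lkap, cell.lsig,
                  xp[nr + 2], cell.lP0)
        ll_prop = _loglik(conf.method, y, cell, lb=lb_p, scal=scal_p)
        if not np.isfinite(ll_prop):
            return False
        dprior = (mix_logpdf_arr(lb_p, hyper)
                  - mix_logpdf_arr(cell.lb, hyper)
                  + norm_logpdf(xp[nr], cfg.mu_dm, cfg.sd_dm)
                  - norm_logpdf(cell.ldm, cfg.mu_dm, cfg.sd_dm)
                  + norm_logpdf(xp[nr + 1], cfg.mu_dp, cfg.sd_dp)
                  - norm_logpdf(cell.ldp, cfg.mu_dp, cfg.sd_dp)
                  + norm_logpdf(xp[nr + 2], cfg.mu_lM0, cfg.sd_lM0)
                  - norm_logpdf(cell.lM0, cfg.mu_lM0, cfg.sd_lM0))
        acc = math.log(rng.random() + 1e-300) < ll_prop - cell.ll + dprior
        if acc:
            cell.lb = lb_p
            cell.ldm = xp[nr]
            cell.ldp = xp[nr + 1]
            cell.lM0 = xp[nr + 2]
            cell.ll = ll_prop
        # adaptation uses the realized chain values
        for v in cell.lb:
            diag_adapt.update_one(0, v)
        diag_adapt.update_one(1, cell.ldm)
        diag_adapt.update_one(2, cell.ldp)
        diag_adapt.update_one(3, cell.lM0)
        return acc

    # block 2: (lat, [lkap], lsig, lP0)
    if kap_free:
        x = np.array([cell.lat, cell.lkap, cell.lsig, cell.lP0])
    else:
        x = np.array([cell.lat, cell.lsig, cell.lP0])
    d = x.size
    L = blk_adapt.proposal_chol()
    adapting = (state.iteration >= conf.adapt_start and L is not None
                and rng.random() > 0.05)
    if adapting:
        xp = x + L @ rng.standard_normal(d)
    else:
        xp = x + conf.fixed_sd * rng.standard_normal(d)
    if np.abs(xp).max() > cfg.log_bound:
        blk_adapt.update(x)
        return False
    if kap_free:
        scal_p = (cell.ldm, cell.ldp, xp[0], xp[1], xp[2], cell.lM0, xp[3])
    else:
        scal_p = (cell.ldm, cell.ldp, xp[0], cell.lkap, xp[1], cell.lM0,
                  xp[2])
    ll_prop = _loglik(conf.method, y, cell, scal=scal_p)
    acc = False
    if np.isfinite(ll_prop):
        scal_cur = (cell.ldm, cell.ldp, cell.lat, cell.lkap, cell.lsig,
                    cell.lM0, cell.lP0)
        dprior = (_scalar_prior(scal_p, hyper, cfg)
                  - _scalar_prior(scal_cur, hyper, cfg))
        acc = math.log(rng.random() + 1e-300) < ll_prop - cell.ll + dprior
        if acc:
            cell.lat = scal_p[2]
            cell.lkap = scal_p[3]
            cell.lsig = scal_p[4]
            cell.lP0 = scal_p[6]
            cell.ll = ll_prop
    if kap_free:
        blk_adapt.update(np.array([cell.lat, cell.lkap, cell.lsig,
                                   cell.lP0]))
    else:
        blk_adapt.update(np.array([cell.lat, cell.lsig, cell.lP0]))
    return acc


def _nig_draw(x: np.ndarray, nig, rng):
    """Posterior (mu, var) draw of a Gaussian mean/variance under the NIG
    conjugate prior; with no data this is a prior draw."""
    n = x.size
    if n == 0:
        var = 1.0 / rng.gamma(nig.a, 1.0 / nig.b)
        mu = rng.normal(nig.m, math.sqrt(var / nig.k0))
        return mu, var
    sx = float(np.sum(x))
    xbar = sx / n
    kn = nig.k0 + n
    mn = (nig.k0 * nig.m + sx) / kn
    an = nig.a + 0.5 * n
    ss = float(np.dot(x, x)) - n * xbar * xbar
    bn = nig.b + 0.5 * max(ss, 0.0) \
        + 0.5 * nig.k0 * n * (xbar - nig.m) ** 2 / kn
    var = 1.0 / rng.gamma(an, 1.0 / bn)
    mu = rng.normal(mn, math.sqrt(var / kn))
    return mu, var


def hyper_draw(h: HyperParams, cfg: PriorConfig, rng, la, lk, ls,
               rates) -> None:
    """Conjugate Gibbs draw of all hyper-parameters given per-cell
    log alpha, log kappa, log sigma values and the pooled log rates
    (mixture allocations are resampled first).  Mutates `h`."""
    h.mu_alpha, h.var_alpha = _nig_draw(la, cfg.nig_alpha, rng)
    h.mu_kappa, h.var_kappa = _nig_draw(lk, cfg.nig_kappa, rng)
    h.mu_sigma, h.var_sigma = _nig_draw(ls, cfg.nig_sigma, rng)
    M = h.n_components
    if rates.size:
        logp = np.empty((rates.size, M))
        for m in range(M):
            sd = math.sqrt(h.beta_vars[m])
            logp[:, m] = (np.log(h.beta_weights[m] + 1e-300)
                          - 0.5 * ((rates - h.beta_means[m]) / sd) ** 2
                          - math.log(sd))
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        uu = rng.random(rates.size)
        z = (uu[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    else:
        z = np.empty(0, dtype=int)
    counts = np.bincount(z, minlength=M)
    h.beta_weights = rng.dirichlet(cfg.dirichlet_conc + counts)
    for m in range(M):
        xm = rates[z == m]
        mu, var = _nig_draw(xm, cfg.nig_beta, rng)
        h.beta_means[m] = mu
        h.beta_vars[m] = var


def hyper_update(state: ChainState) -> None:
    """Hyper-parameter Gibbs step on a ChainState (CellState cells)."""
    if not state.config.update_hypers:
        return
    la = np.array([c.lat - c.lkap for c in state.cells])
    lk = np.array([c.lkap for c in state.cells])
    ls = np.array([c.lsig for c in state.cells])
    rates = (np.concatenate([c.lb for c in state.cells])
             if state.cells else np.empty(0))
    hyper_draw(state.hyper, state.priors, state.rng, la, lk, ls, rates)


def csmc_update(state: ChainState, ci: int) -> None:
    """Particle-Gibbs refresh of one cell's latent path (BDA only)."""
    cell = state.cells[ci]
    y = state.data[ci]
    seed = int(state.rng.integers(2 ** 31 - 1))
    M, P, _, _ = csmc_core(
        y.values, y.times, cell.s, np.exp(cell.lb), math.exp(cell.ldm),
        math.exp(cell.ldp), math.exp(cell.lat), math.exp(cell.lkap),
        math.exp(cell.lsig), math.exp(cell.lM0), math.exp(cell.lP0),
        cell.path.M, cell.path.P, state.config.n_particles, seed, True)
    cell.path = LatentPath(M=M, P=P)
    cell.ll = _loglik("bda", y, cell)


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _init_cell(y: TimeSeries, hyper: HyperParams, cfg: PriorConfig,
               conf: MCMCConfig, kappa_fixed: float | None,
               rng) -> CellState:
    ybar = max(float(np.mean(y.values)), 1.0)
    lkap = math.log(kappa_fixed) if kappa_fixed is not None \
        else hyper.mu_kappa
    lat = hyper.mu_alpha + lkap
    dm = math.exp(cfg.mu_dm)
    dp = math.exp(cfg.mu_dp)
    beta0 = max(ybar * dm * dp / math.exp(lat), 0.1)
    # rough noise estimate from first differences
    dif = np.diff(y.values)
    sig0 = max(float(np.std(dif)) / math.sqrt(2.0), 1e-2)
    cell = CellState(
        s=np.empty(0),
        lb=np.array([math.log(beta0)]),
        ldm=cfg.mu_dm, ldp=cfg.mu_dp, lat=lat, lkap=lkap,
        lsig=math.log(sig0),
        lM0=math.log(max(beta0 / dm, 0.5)),
        lP0=math.log(max(float(y.values[0]), 1.0)),
    )
    return cell


def run_chain(data, priors: PriorConfig, config: MCMCConfig,
              hyper: HyperParams | None = None,
              progress: bool = False) -> PosteriorStore:
    """Run the full Gibbs sampler on a collection of cells.

    `data` is a list of TimeSeries sharing a common observation window.
    Returns the thinned posterior store.
    """
    data = list(data)
    if not data:
        raise ValueError("need at least one cell")
    t0s = [y.times[0] for y in data]
    t1s = [y.times[-1] for y in data]
    if max(t0s) >= min(t1s):
        raise ValueError("cell time grids do not overlap")
    if config.method not in ("lna", "bda"):
        raise ValueError("method must be 'lna' or 'bda'")
    if config.kappa_mode not in ("free", "fixed"):
        raise ValueError("kappa_mode must be 'free' or 'fixed'")
    if config.kappa_mode == "fixed" and config.kappa_values is None:
        raise ValueError("kappa_mode='fixed' requires kappa_values")

    rng = np.random.default_rng(config.seed)
    if hyper is None:
        # data-scale-aware starting hierarchy
        ybar = np.mean([np.mean(y.values) for y in data])
        lb0 = math.log(max(ybar, 1.0) * math.exp(priors.mu_dm)
                       * math.exp(priors.mu_dp))
        hyper = HyperParams(beta_means=np.array([lb0 - 1.5, lb0 + 0.5]),
                            beta_vars=np.array([1.0, 1.0]),
                            mu_dm=priors.mu_dm, var_dm=priors.sd_dm ** 2,
                            mu_dp=priors.mu_dp, var_dp=priors.sd_dp ** 2)

    from . import _kernels
    from .priors import _pk_table

    kap_free = config.kappa_mode == "free"
    d2 = 4 if kap_free else 3
    kmax = priors.k_max
    mode = (2 if config.flat_likelihood
            else (0 if config.method == "lna" else 1))
    _kernels.seed_rng(np.uint32(rng.integers(2 ** 31 - 1)))

    pv = np.array([priors.mu_dm, priors.sd_dm, priors.mu_dp, priors.sd_dp,
                   priors.mu_lM0, priors.sd_lM0, priors.mu_lP0,
                   priors.sd_lP0, priors.horizon, priors.min_sep,
                   priors.log_bound, priors.move_sd, config.fixed_sd])
    pk_tab = _pk_table(priors)

    # per-cell kernel state: padded switch arrays plus scalar vectors
    n_cells = len(data)
    S_pad, LB_pad, KD, SCAL, LL, MP, PP = [], [], [], [], [], [], []
    DN, DMEAN, DM2 = [], [], []
    BCNT, BMEAN, BM2, CHOL = [], [], [], []
    empty = np.empty(0)
    for i, y in enumerate(data):
        kf = (None if kap_free
              else float(np.asarray(config.kappa_values).ravel()[i]))
        cell = _init_cell(y, hyper, priors, config, kf, rng)
        s_pad = np.zeros(kmax + 1)
        lb_pad = np.zeros(kmax + 2)
        s_pad[:cell.k] = cell.s
        lb_pad[:cell.k + 1] = cell.lb
        scal = np.array([cell.ldm, cell.ldp, cell.lat, cell.lkap,
                         cell.lsig, cell.lM0, cell.lP0])
        if config.method == "bda":
            path = initial_path(y, _cell_params(cell, priors.horizon))
            MP.append(path.M.copy())
            PP.append(path.P.copy())
        else:
            MP.append(empty)
            PP.append(empty)
        S_pad.append(s_pad)
        LB_pad.append(lb_pad)
        KD.append(np.array([cell.k], dtype=np.int64))
        SCAL.append(scal)
        ll0 = _kernels._ll_nb(mode, y.values, y.times, s_pad, cell.k,
                              lb_pad, scal, MP[-1], PP[-1])
        if not np.isfinite(ll0):
            raise RuntimeError(f"non-finite initial likelihood, cell {i}")
        LL.append(np.array([ll0]))
        DN.append(np.zeros(4))
        DMEAN.append(np.zeros(4))
        DM2.append(np.zeros(4))
        BCNT.append(np.zeros(3, dtype=np.int64))
        BMEAN.append(np.zeros(d2))
        BM2.append(np.zeros((d2, d2)))
        CHOL.append(np.zeros((d2, d2)))

    thin = config.thin or max(1, config.n_iter // 4000)
    acc = {"rj": np.zeros(n_cells), "block1": np.zeros(n_cells),
           "block2": np.zeros(n_cells)}
    store_k = [[] for _ in range(n_cells)]
    store_s = [[] for _ in range(n_cells)]
    store_lb = [[] for _ in range(n_cells)]
    store_par = [[] for _ in range(n_cells)]
    store_hyp = []
    kfree_i = 1 if kap_free else 0

    for it in range(config.n_iter):
        if config.update_hypers:
            la = np.array([SCAL[c][2] - SCAL[c][3] for c in range(n_cells)])
            lk = np.array([SCAL[c][3] for c in range(n_cells)])
            ls = np.array([SCAL[c][4] for c in range(n_cells)])
            rates = np.concatenate([LB_pad[c][:KD[c][0] + 1]
                                    for c in range(n_cells)])
            hyper_draw(hyper, priors, rng, la, lk, ls, rates)
        hyp = np.array([hyper.mu_alpha, hyper.var_alpha, hyper.mu_kappa,
                        hyper.var_kappa, hyper.mu_sigma, hyper.var_sigma])
        for ci in range(n_cells):
            y = data[ci]
            a1, a2, a3 = _kernels.gibbs_cell_sweep(
                mode, y.values, y.times, S_pad[ci], LB_pad[ci], KD[ci],
                SCAL[ci], LL[ci], MP[ci], PP[ci], hyper.beta_weights,
                hyper.beta_means, hyper.beta_vars, pk_tab, pv, hyp,
                kmax, kfree_i, it, config.adapt_start,
                DN[ci], DMEAN[ci], DM2[ci],
                BCNT[ci], BMEAN[ci], BM2[ci], CHOL[ci])
            acc["rj"][ci] += a1
            acc["block1"][ci] += a2
            acc["block2"][ci] += a3
            if config.method == "bda":
                k = int(KD[ci][0])
                scal = SCAL[ci]
                Mn, Pn, _, _ = _kernels.csmc_core(
                    y.values, y.times, S_pad[ci][:k],
                    np.exp(LB_pad[ci][:k + 1]), math.exp(scal[0]),
                    math.exp(scal[1]), math.exp(scal[2]),
                    math.exp(scal[3]), math.exp(scal[4]),
                    math.exp(scal[5]), math.exp(scal[6]),
                    MP[ci], PP[ci], config.n_particles,
                    np.uint32(rng.integers(2 ** 31 - 1)), True)
                MP[ci] = Mn
                PP[ci] = Pn
                LL[ci][0] = _kernels._ll_nb(1, y.values, y.times,
                                            S_pad[ci], k, LB_pad[ci],
                                            scal, Mn, Pn)
        if (it + 1) % thin == 0:
            h = hyper
            store_hyp.append([h.mu_alpha, h.var_alpha, h.mu_kappa,
                              h.var_kappa, h.mu_sigma, h.var_sigma,
                              h.beta_weights[0], h.beta_means[0],
                              h.beta_vars[0], h.beta_weights[-1],
                              h.beta_means[-1], h.beta_vars[-1]])
            for ci in range(n_cells):
                k = int(KD[ci][0])
                store_k[ci].append(k)
                store_s[ci].append(S_pad[ci][:k].copy())
                store_lb[ci].append(LB_pad[ci][:k + 1].copy())
                store_par[ci].append(SCAL[ci].copy())
        if progress and (it + 1) % max(1, config.n_iter // 20) == 0:
            print(f"iter {it + 1}/{config.n_iter}  "
                  f"k={[int(KD[c][0]) for c in range(n_cells)]}")

    return PosteriorStore(
        method=config.method, n_iter=config.n_iter, thin=thin,
        cell_ids=[y.cell_id for y in data],
        k=[np.array(v) for v in store_k],
        switch_times=store_s, log_rates=store_lb,
        params=[np.array(v) for v in store_par],
        hyper=np.array(store_hyp),
        accept={k2: v / config.n_iter for k2, v in acc.items()},
    )


def _cell_params(cell: CellState, horizon: float):
    from .model import CellParams, SwitchFunction
    kap = math.exp(cell.lkap)
    return CellParams(
        SwitchFunction(cell.s, np.exp(cell.lb), horizon),
        alpha=math.exp(cell.lat) / kap, delta_m=math.exp(cell.ldm),
        delta_p=math.exp(cell.ldp), kappa=kap,
        sigma_eps=math.exp(cell.lsig), M0=math.exp(cell.lM0),
        P0=math.exp(cell.lP0) / kap)


def posterior_profile(store: PosteriorStore, grid, q=0.5,
                      burn_frac: float = 0.5) -> np.ndarray:
    """Pointwise posterior quantile of the transcription rate beta(t).

    Returns (n_cells, len(grid)); q may be a scalar or a sequence (then
    the result has an extra leading axis per quantile).
    """
    grid = np.asarray(grid, dtype=float)
    if store.n_draws == 0:
        raise ValueError("empty posterior store")
    sl = store.burn_slice(burn_frac)
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.empty((qs.size, len(store.k), grid.size))
    for ci in range(len(store.k)):
        ss = store.switch_times[ci][sl]
        bb = store.log_rates[ci][sl]
        prof = np.empty((len(ss), grid.size))
        for r, (s, lb) in enumerate(zip(ss, bb)):
            idx = np.searchsorted(s, grid, side="right")
            prof[r] = np.exp(lb)[idx]
        out[:, ci] = np.quantile(prof, qs, axis=0)
    return out[0] if np.isscalar(q) or qs.size == 1 else out
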