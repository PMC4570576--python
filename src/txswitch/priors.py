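"""Prior configuration and densities for the switch-model sampler.

Priors (all on the log scale for positive parameters):

* number of switches k: truncated Poisson, p(k) proportional to
  lambda^k / k! on {0..k_max}; combined with the order-statistics prior
  on the times below this is a homogeneous Poisson-process prior on
  switching events (rate lambda per recording window), whose
  log-factorial tail keeps changepoints from chasing intrinsic noise;
* switch times given k: order statistics of uniforms on (0, horizon) with
  a minimum separation `min_sep` between switches and from both ends, so
  p(s | k) = k! / (horizon - (k+1) min_sep)^k on the constrained region;
* log rates: the hierarchical Gaussian mixture (marginalized over the
  component label);
* log alpha = log(alpha~/kappa), log kappa, log sigma_eps: Gaussian
  hierarchies; log delta_m, log delta_p: fixed informative Gaussians;
* log M0, log P~0: fixed Gaussians (weakly informative, scale set from
  the data at configuration time);
* hard bounds +-`log_bound` on every log parameter, required for the
  ergodicity of the adaptive proposals (bounded support).

Hyper-priors are conjugate normal-inverse-gamma (NIG) for every Gaussian
hierarchy and symmetric Dirichlet for the mixture weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import HyperParams

__all__ = ["NIG", "PriorConfig", "log_prior_k", "log_prior_s",
           "mix_logpdf", "mix_sample"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NIG:
    """Normal-inverse-gamma hyper-prior: sigma^2 ~ IG(a, b),
    mu | sigma^2 ~ N(m, sigma^2 / k0)."""

    m: float = 0.0
    k0: float = 0.01
    a: float = 2.0
    b: float = 0.5


@dataclass
class PriorConfig:
    horizon: float = 42.0
    # switch configuration
    poisson_k: float = 1.0
    k_max: int = 20
    min_sep: float = 0.25
    # fixed informative degradation priors (log scale)
    mu_dm: float = 0.0
    sd_dm: float = 0.1
    mu_dp: float = math.log(0.7)
    sd_dp: float = 0.1
    # initial-state priors (log scale)
    mu_lM0: float = math.log(10.0)
    sd_lM0: float = 1.5
    mu_lP0: float = math.log(30.0)
    sd_lP0: float = 1.5
    # hyper-priors
    nig_alpha: NIG = field(default_factory=NIG)
    nig_kappa: NIG = field(default_factory=NIG)
    nig_sigma: NIG = field(default_factory=NIG)
    # keep the mixture components from sharpening onto clustered rates
    # (a collapsed component would subsidise spurious switches)
    nig_beta: NIG = field(default_factory=lambda: NIG(m=1.5, k0=0.01,
                                                      a=2.0, b=2.0))
    dirichlet_conc: float = 1.0
    # adaptive-MH ergodicity bound on |log parameter|
    log_bound: float = 20.0
    # random-walk sd for the switch-time move
    move_sd: float = 1.0

    def __post_init__(self):
        if self.poisson_k <= 0:
            raise ValueError("poisson_k must be > 0")
        if self.k_max * 2 * self.min_sep >= self.horizon:
            raise ValueError("k_max switches cannot fit the horizon")


_PK_CACHE: dict = {}


def _pk_table(cfg: PriorConfig) -> np.ndarray:
    key = (cfg.poisson_k, cfg.k_max)
    tab = _PK_CACHE.get(key)
    if tab is None:
        lam = cfg.poisson_k
        terms = np.array([j * math.log(lam) - math.lgamma(j + 1)
                          for j in range(cfg.k_max + 1)])
        mx = terms.max()
        tab = terms - (mx + math.log(np.exp(terms - mx).sum()))
        _PK_CACHE[key] = tab
    return tab


def log_prior_k(k: int, cfg: PriorConfig) -> float:
    if k < 0 or k > cfg.k_max:
        return -np.inf
    return float(_pk_table(cfg)[k])


def log_prior_s(k: int, cfg: PriorConfig) -> float:
    """Log density of the switch-time vector given k (constant on the
    constrained region): log k! - k log(horizon - (k+1) min_sep)."""
    if k == 0:
        return 0.0
    span = cfg.horizon - (k + 1) * cfg.min_sep
    if span <= 0:
        return -np.inf
    return math.lgamma(k + 1) - k * math.log(span)


def s_valid(s: np.ndarray, cfg: PriorConfig) -> bool:
    if s.size == 0:
        return True
    edges = np.concatenate(([0.0], s, [cfg.horizon]))
    return bool((np.diff(edges) >= cfg.min_sep - 1e-12).all())


def norm_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG2PI


def mix_logpdf(x: float, hyper: HyperParams) -> float:
    """Marginal mixture density of one log rate under the hierarchy."""
    w = hyper.beta_weights
    mu = hyper.beta_means
    v = hyper.beta_vars
    acc = 0.0
    for m in range(w.size):
        z = (x - mu[m]) / math.sqrt(v[m])
        acc += w[m] * math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi * v[m])
    if acc <= 0:
        return -np.inf
    return math.log(acc)


def mix_logpdf_arr(x: np.ndarray, hyper: HyperParams) -> float:
    """Sum of marginal mixture log densities over an array of log rates."""
    x = np.asarray(x, dtype=float)
    w = hyper.beta_weights
    mu = hyper.beta_means
    v = hyper.beta_vars
    z = (x[:, None] - mu[None, :])
    dens = (w / np.sqrt(2 * math.pi * v)
            * np.exp(-0.5 * z * z / v)).sum(axis=1)
    if (dens <= 0).any():
        return -np.inf
    return float(np.log(dens).sum())


def mix_sample(hyper: HyperParams, rng) -> float:
    m = rng.choice(hyper.beta_weights.size, p=hyper.beta_weights)
    return float(rng.normal(hyper.beta_means[m],
                            math.sqrt(hyper.beta_vars[m])))
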