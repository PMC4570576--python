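"""Core gene-expression model: reaction network, switch function, parameters.

The model is the standard two-stage description of gene expression with a
time-varying transcription rate,

    DNA --beta(t)--> mRNA,    mRNA --delta_m--> 0,
    mRNA --alpha--> mRNA + Protein,    Protein --delta_p--> 0,

where beta(t) is piecewise constant with an unknown number k of switch
times.  Observations are noisy scaled protein levels, Y = kappa*P + eps,
eps ~ N(0, sigma_eps^2).  Because only kappa*P is observed, inference works
on the reparameterized quantities alpha~ = kappa*alpha and P~ = kappa*P.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ReactionNetwork",
    "SwitchFunction",
    "CellParams",
    "HyperParams",
    "TimeSeries",
    "GENE_NETWORK",
    "gene_network",
    "hazard_vector",
    "mass_action_hazards",
    "switch_rate_at",
    "complete_data_loglik",
]


@dataclass(frozen=True)
class ReactionNetwork:
    """A mass-action stochastic reaction network.

    `reactants` and `products` are (n_reactions, n_species) integer
    matrices; the stoichiometry is their difference.  `system_size` is the
    thermodynamic volume Omega; we work in absolute molecule numbers so it
    defaults to 1 (the measurement scale kappa absorbs all unit changes).
    """

    reactants: np.ndarray
    products: np.ndarray
    rate_constants: np.ndarray
    system_size: float = 1.0

    def __post_init__(self):
        P = np.asarray(self.reactants, dtype=int)
        Q = np.asarray(self.products, dtype=int)
        if P.shape != Q.shape:
            raise ValueError("reactant and product matrices must share shape")
        if (P < 0).any() or (Q < 0).any():
            raise ValueError("stoichiometric coefficients must be >= 0")
        th = np.asarray(self.rate_constants, dtype=float)
        if (th < 0).any():
            raise ValueError("rate constants must be non-negative")
        object.__setattr__(self, "reactants", P)
        object.__setattr__(self, "products", Q)
        object.__setattr__(self, "rate_constants", th)

    @property
    def stoichiometry(self) -> np.ndarray:
        """S = Q - P, with column v_j the state change of reaction j."""
        return (self.products - self.reactants).T

    @property
    def n_reactions(self) -> int:
        return self.reactants.shape[0]

    @property
    def n_species(self) -> int:
        return self.reactants.shape[1]


def gene_network(beta: float, delta_m: float, alpha: float,
                 delta_p: float) -> ReactionNetwork:
    """The 4-reaction gene-expression network on species (M, P)."""
    reactants = np.array([[0, 0], [1, 0], [1, 0], [0, 1]])
    products = np.array([[1, 0], [0, 0], [1, 1], [0, 0]])
    return ReactionNetwork(reactants, products,
                           np.array([beta, delta_m, alpha, delta_p]))


GENE_NETWORK = gene_network(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SwitchFunction:
    """Piecewise-constant transcription rate.

    beta(t) = rates[i] on [times[i-1], times[i]) with times[-1] := 0 and
    times[k] := horizon; intervals are left-closed/right-open, so at a
    switch time the post-switch rate applies.
    """

    times: np.ndarray
    rates: np.ndarray
    horizon: float

    def __post_init__(self):
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if r.size != t.size + 1:
            raise ValueError("need exactly k+1 rates for k switch times")
        if t.size and (np.diff(t) <= 0).any():
            raise ValueError("switch times must be strictly increasing")
        if t.size and (t[0] <= 0 or t[-1] >= self.horizon):
            raise ValueError("switch times must lie strictly inside (0, horizon)")
        if (r <= 0).any():
            raise ValueError("transcription rates must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "rates", r)

    @property
    def k(self) -> int:
        return self.times.size

    def __call__(self, t: float) -> float:
        return switch_rate_at(self, t)

    def integral(self) -> float:
        """Integral of beta over [0, horizon]."""
        edges = np.concatenate(([0.0], self.times, [self.horizon]))
        return float(np.sum(self.rates * np.diff(edges)))

    @classmethod
    def constant(cls, rate: float, horizon: float) -> "SwitchFunction":
        return cls(np.empty(0), np.array([rate]), horizon)


def switch_rate_at(fn: SwitchFunction, t: float) -> float:
    """beta(t) under the [s_{i-1}, s_i) convention."""
    if t < 0 or t > fn.horizon:
        raise ValueError(f"time {t} outside [0, {fn.horizon}]")
    return float(fn.rates[np.searchsorted(fn.times, t, side="right")])


@dataclass(frozen=True)
class CellParams:
    """All kinetic, initial-state and measurement parameters of one cell."""

    switch_fn: SwitchFunction
    alpha: float       # proteins per mRNA per hour
    delta_m: float     # mRNA degradation, per hour
    delta_p: float     # protein degradation, per hour
    kappa: float       # intensity units per protein
    sigma_eps: float   # measurement noise sd, intensity units
    M0: float = 0.0    # initial mRNA copies
    P0: float = 0.0    # initial protein copies

    def __post_init__(self):
        for name in ("alpha", "delta_m", "delta_p", "kappa", "sigma_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.M0 < 0 or self.P0 < 0:
            raise ValueError("initial state must be >= 0")

    @property
    def alpha_tilde(self) -> float:
        """kappa * alpha, the translation rate on the intensity scale."""
        return self.kappa * self.alpha

    @property
    def P0_tilde(self) -> float:
        """kappa * P0, the initial protein level on the intensity scale."""
        return self.kappa * self.P0

    def with_(self, **kw) -> "CellParams":
        return replace(self, **kw)


@dataclass
class HyperParams:
    """Population-level hierarchy.

    Log-normal hierarchies on alpha, kappa and sigma_eps; a finite Gaussian
    mixture on log transcription rates (default two components: the high
    and low transcriptional states); fixed informative log-normal
    distributions for the degradation rates.
    """

    mu_alpha: float = 0.0
    var_alpha: float = 1.0
    mu_kappa: float = 0.0
    var_kappa: float = 1.0
    mu_sigma: float = 0.0
    var_sigma: float = 1.0
    beta_weights: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    beta_means: np.ndarray = field(default_factory=lambda: np.array([1.0, 3.0]))
    beta_vars: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))
    mu_dm: float = 0.0
    var_dm: float = 0.01
    mu_dp: float = np.log(0.7)
    var_dp: float = 0.01

    def __post_init__(self):
        w = np.asarray(self.beta_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for v in (self.var_alpha, self.var_kappa, self.var_sigma,
                  self.var_dm, self.var_dp):
            if v <= 0:
                raise ValueError("variances must be > 0")
        if (np.asarray(self.beta_vars) <= 0).any():
            raise ValueError("variances must be > 0")
        self.beta_weights = w
        self.beta_means = np.asarray(self.beta_means, dtype=float)
        self.beta_vars = np.asarray(self.beta_vars, dtype=float)

    @property
    def n_components(self) -> int:
        return self.beta_weights.size


@dataclass(frozen=True)
class TimeSeries:
    """One cell's observed intensity series."""

    times: np.ndarray
    values: np.ndarray
    cell_id: str = "cell0"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be equal-length vectors")
        if t.size and ((np.diff(t) <= 0).any() or t[0] < 0):
            raise ValueError("times must be non-negative and strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


def hazard_vector(state: Sequence[float], params: CellParams,
                  t: float) -> np.ndarray:
    """Mass-action hazards (beta(t), delta_m*M, alpha*M, delta_p*P)."""
    M, P = state
    if M < 0 or P < 0:
        raise ValueError("state components must be >= 0")
    beta = switch_rate_at(params.switch_fn, t)
    return np.array([beta, params.delta_m * M, params.alpha * M,
                     params.delta_p * P])


def mass_action_hazards(network: ReactionNetwork,
                        state: Sequence[float]) -> np.ndarray:
    """Generic mass-action hazards h_j = theta_j * prod_k C(x_k, P_jk)."""
    x = np.asarray(state, dtype=float)
    if (x < 0).any():
        raise ValueError("state components must be >= 0")
    h = np.array(network.rate_constants, dtype=float)
    for j in range(network.n_reactions):
        for k in range(network.n_species):
            p = network.reactants[j, k]
            if p == 0:
                continue
            # binomial coefficient C(x_k, p) for integer p
            c = 1.0
            for i in range(p):
                c *= (x[k] - i) / (i + 1)
            h[j] *= max(c, 0.0)
    return h


def complete_data_loglik(traj, params: CellParams) -> float:
    """Log density of a fully observed reaction path.

    Sum of log hazards of the realized reactions minus the integrated total
    hazard (the survival terms between consecutive events).  Used to test
    the simulator; inference never observes complete paths.

    `traj` is an ExactTrajectory (see txswitch.ssa).
    """
    fn = params.switch_fn
    horizon = fn.horizon
    # event times plus segment boundaries partition [0, horizon] into
    # intervals of constant hazard
    times = np.asarray(traj.times, dtype=float)
    if times.size and (times[0] < 0 or times[-1] > horizon):
        raise ValueError("reaction times outside [0, horizon]")

    ll = 0.0
    state = np.array(traj.x0, dtype=float)
    t_prev = 0.0
    ev = 0
    n_ev = times.size
    # walk through the union of event times and switch times
    boundaries = np.concatenate((fn.times, [horizon]))
    bi = 0
    while True:
        t_next_event = times[ev] if ev < n_ev else np.inf
        t_next_bound = boundaries[bi] if bi < boundaries.size else np.inf
        t_next = min(t_next_event, t_next_bound)
        if not np.isfinite(t_next):
            break
        h = hazard_vector(state, params, t_prev)
        ll -= h.sum() * (t_next - t_prev)
        if t_next_event <= t_next_bound:
            j = int(traj.types[ev])
            hj = hazard_vector(state, params, t_next)[j - 1]
            if hj <= 0:
                return -np.inf
            ll += np.log(hj)
            if j == 1:
                state[0] += 1
            elif j == 2:
                state[0] -= 1
            elif j == 3:
                state[1] += 1
            else:
                state[1] -= 1
            ev += 1
        if t_next_bound <= t_next_event:
            bi += 1
            if t_next_bound >= horizon:
                break
        t_prev = t_next
    return float(ll)
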