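# txswitch

Bayesian inference of stochastic transcriptional switching from
single-cell reporter imaging time series.

Fluorescent or luminescent reporter constructs make transcription of a
gene of interest indirectly observable as a noisy light-intensity time
course, one trace per cell.  `txswitch` back-calculates from those traces
to the transcriptional activity itself, modelled as a piecewise-constant
rate ("switch") function with an unknown number of changes — a
multi-state generalization of the classical on/off telegraph picture of
bursty transcription.

## Model

The latent dynamics are the standard two-stage gene-expression reaction
network, treated as a Markov jump process on copy numbers
**X** = (M, P):

```
DNA --beta(t)--> mRNA        mRNA --delta_m--> 0
mRNA --alpha--> mRNA + P     P    --delta_p--> 0
```

with transcription rate beta(t) = beta_i on [s_{i-1}, s_i), where the
number k, locations s_1 < ... < s_k and levels beta_0..beta_k of the
switches are unknown.  Measurements are Y_t = kappa P_t + eps_t with
eps_t ~ N(0, sigma_eps^2): `kappa` converts protein copies to intensity
units.  Inference targets the per-cell parameter vector
(beta(.), alpha, delta_m, delta_p, kappa, sigma_eps, M0, P0) under a
hierarchical model that shares log-normal population distributions of
alpha, kappa, sigma_eps — and a two-component mixture for the log rates —
across cells, using the reparameterization alpha~ = kappa alpha,
P~ = kappa P to break the alpha–kappa ridge.

Because the exact transition densities are intractable, two
approximations are provided, both embedded in the same state-space
framework:

* **LNA** — the linear noise approximation; Gaussian transitions whose
  first two moments are exact for this affine-hazard network, giving the
  marginal likelihood in closed form via the Kalman filter;
* **BDA** — a model-specific birth–death decomposition: the mRNA
  transition is the exact Binomial-thinning + Poisson-immigration law,
  the protein transition is an immigration–death law conditioned on the
  interval-start mRNA count, and both are moment-matched by normal
  densities truncated to the positive half-line.  The latent path is then
  sampled by particle Gibbs (conditional SMC).

The posterior over switch configurations is explored by reversible-jump
MCMC (add / delete / move a switch) combined with adaptive random-walk
Metropolis blocks and conjugate hyper-parameter updates.  An exact
Gillespie simulator, a truncated chemical-master-equation solver (test
oracle) and simulation-envelope comparisons of all approximations are
included.

## Worked example

```python
import numpy as np
from txswitch.synthetic import generate_dataset, recovery_report
from txswitch.priors import PriorConfig
from txswitch.mcmc import MCMCConfig, run_chain, posterior_profile

# ten cells from the exact jump process: rates (6, 20, 2) mRNA/h,
# switches at t = 12 h and 20 h, sampled every 15 min for 42 h
data, truth = generate_dataset(10, preset="scenario1", seed=42)

priors = PriorConfig(mu_dm=0.0, sd_dm=0.1,          # log delta_m ~ N(log 1, 0.1^2)
                     mu_dp=np.log(0.7), sd_dp=0.1)  # log delta_p ~ N(log 0.7, 0.1^2)
store = run_chain(data, priors, MCMCConfig(method="lna",
                                           n_iter=200_000, seed=7))

rep = recovery_report(truth, store)
print(rep["frac_modal_k_correct"], rep["frac_switch_covered"])
# 0.8 1.0

prof = posterior_profile(store, np.arange(0, 42.5, 0.5))
print(prof[0, [10, 30, 60]].round(1))   # posterior median beta(t) at 5, 15, 30 h
# [ 3.3 11.4  2. ]
```

With informative degradation priors the sampler recovers the true switch
count (k = 2) as the posterior mode for 8 of 10 cells and the 95%
credible intervals of the switch times cover the truth for all 10.  The
posterior-median profile of the first cell shows the three generating
levels (truth 6, 20, 2 mRNA/h) up to the partial trade-off between the
absolute rate scale and the translation rate — under the LNA the product
alpha~ beta is what the data pin down sharply, the hierarchy across
cells resolving the rest.  For the BDA workflow, run the LNA first, fix `kappa` at its
posterior median (`kappa_mode="fixed"`), and rerun with
`method="bda"`.

A CLI mirrors this workflow: `txswitch simulate`, `txswitch fit`,
`txswitch profile`, `txswitch diagnose` (see `txswitch --help`).

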