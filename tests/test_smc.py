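import math

import numpy as np
import pytest

from txswitch import _kernels
from txswitch.kalman import kalman_loglik
from txswitch.model import CellParams, SwitchFunction, TimeSeries
from txswitch.smc import LatentPath, csmc_sweep, initial_path, smc_loglik


@pytest.fixture()
def toy(scenario1_params):
    grid = np.arange(0.0, 5.25, 0.25)
    rng = np.random.default_rng(9)
    from txswitch.ssa import simulate_on_grid
    path = simulate_on_grid(scenario1_params, grid, seed=9)
    y = path[:, 1] + rng.normal(0, 2.0, grid.size)
    return TimeSeries(grid, y)


def test_single_particle_returns_reference(toy, scenario1_params):
    """Conditional SMC with one particle can only follow the pinned path."""
    ref = initial_path(toy, scenario1_params)
    out = csmc_sweep(toy, scenario1_params, ref, n_particles=1, seed=4)
    np.testing.assert_array_equal(out.M, ref.M)
    np.testing.assert_array_equal(out.P, ref.P)


def test_reference_path_survives_resampling(toy, scenario1_params):
    """With an absurd reference the sweep must still return a valid path
    (the conditional kernel never loses the reference slot)."""
    T = len(toy) - 1
    ref = LatentPath(M=np.full(T, 40.0), P=np.full(T, 400.0))
    out = csmc_sweep(toy, scenario1_params, ref, n_particles=50, seed=1)
    assert np.all(out.M > 0) and np.all(out.P > 0)


def test_uninformative_likelihood_gives_uniform_weights(
        toy, scenario1_params):
    """sigma -> infinity: every particle explains the data equally well,
    so the ESS stays at the particle count."""
    p = scenario1_params.with_(sigma_eps=1e6)
    ref = initial_path(toy, p)
    fn = p.switch_fn
    _, _, _, min_ess = _kernels.csmc_core(
        toy.values, toy.times, fn.times, fn.rates, p.delta_m, p.delta_p,
        p.alpha_tilde, p.kappa, p.sigma_eps, float(p.M0),
        float(p.P0_tilde), ref.M, ref.P, 64, 3, True)
    assert min_ess == pytest.approx(64, rel=1e-6)


def test_ess_stays_healthy_with_conjugate_proposal(toy, scenario1_params):
    """The locally optimal P~ proposal keeps the ESS well above Np/10 on
    scenario-1 synthetic data."""
    p = scenario1_params
    ref = initial_path(toy, p)
    fn = p.switch_fn
    esses = []
    for seed in range(20):
        _, _, _, min_ess = _kernels.csmc_core(
            toy.values, toy.times, fn.times, fn.rates, p.delta_m,
            p.delta_p, p.alpha_tilde, p.kappa, p.sigma_eps, float(p.M0),
            float(p.P0_tilde), ref.M, ref.P, 100, seed, True)
        esses.append(min_ess)
    assert np.median(esses) > 10


class TestSmcLoglik:
    def test_single_observation_case(self, scenario1_params):
        """With one observation the estimate is exactly the measurement
        density at the pinned initial state."""
        y = TimeSeries(np.array([0.0]), np.array([24.0]))
        est = smc_loglik(y, scenario1_params, n_particles=10, seed=0)
        s = scenario1_params.sigma_eps
        expected = (-0.5 * math.log(2 * math.pi * s * s)
                    - 0.5 * (24.0 - 26.0) ** 2 / s ** 2)
        assert est == pytest.approx(expected, rel=1e-12)

    def test_linear_gaussian_surrogate_unbiased(self, scenario1_params):
        """Mean of repeated SMC evidence estimates matches the Kalman
        value on the LNA-Gaussian model within 3 SE (scaled down)."""
        grid = np.arange(0.0, 3.25, 0.25)
        from txswitch.lna import simulate_lna_path
        p = scenario1_params.with_(sigma_eps=5.0)
        path = simulate_lna_path(p, grid, seed=21, scaled=True)[0]
        rng = np.random.default_rng(2)
        y = TimeSeries(grid, path[:, 1] + rng.normal(0, 5.0, grid.size))
        kl = kalman_loglik(y, p, restart=False).loglik
        est = np.array([smc_loglik(y, p, 100, seed=300 + i, model="lna")
                        for i in range(60)])
        se = est.std(ddof=1) / math.sqrt(est.size)
        assert abs(est.mean() - kl) < 3 * se

    def test_more_particles_reduce_variance(self, toy, scenario1_params):
        small = [smc_loglik(toy, scenario1_params, 10, seed=i)
                 for i in range(30)]
        big = [smc_loglik(toy, scenario1_params, 200, seed=i)
               for i in range(30)]
        assert np.std(big) < np.std(small)

    def test_unknown_model_rejected(self, toy, scenario1_params):
        with pytest.raises(ValueError):
            smc_loglik(toy, scenario1_params, model="cle")


class TestReferenceImplementation:
    def test_particle_set_invariants(self, toy, scenario1_params):
        from txswitch.smc import csmc_sweep_reference
        ref = initial_path(toy, scenario1_params)
        path, ps = csmc_sweep_reference(toy, scenario1_params, ref,
                                        n_particles=30, seed=2)
        np.testing.assert_allclose(ps.weights.sum(axis=1), 1.0,
                                   rtol=1e-12)
        assert ps.ancestors.min() >= 0
        assert ps.ancestors.max() < 30
        # the reference path survives every resampling step
        assert np.all(ps.ancestors[:, 0] == 0)
        np.testing.assert_array_equal(ps.M[:, 0], ref.M)
        assert np.all(path.M > 0) and np.all(path.P > 0)

    def test_agrees_with_kernel_on_enumerable_toy(self):
        """The Python reference sweep targets the same conditional as
        the compiled kernel: their long-run draws of (M_1, P~_1) agree
        in distribution on a coarse grid."""
        from txswitch.smc import csmc_sweep_reference
        fn = SwitchFunction.constant(2.0, 5.0)
        pars = CellParams(fn, alpha=3.0, delta_m=1.0, delta_p=0.7,
                          kappa=1.0, sigma_eps=1.0, M0=3, P0=5)
        y = TimeSeries(np.array([0.0, 1.0, 2.0]),
                       np.array([5.2, 9.5, 7.8]))
        n = 15_000
        a = np.zeros((9, 9))
        b = np.zeros((9, 9))
        cur1 = initial_path(y, pars)
        cur2 = initial_path(y, pars)
        for i in range(n):
            cur1 = csmc_sweep(y, pars, cur1, n_particles=25, seed=i)
            cur2, _ = csmc_sweep_reference(y, pars, cur2,
                                           n_particles=25, seed=i)
            a[min(int(cur1.M[0] / 2), 8), min(int(cur1.P[0] / 2), 8)] += 1
            b[min(int(cur2.M[0] / 2), 8), min(int(cur2.P[0] / 2), 8)] += 1
        tv = 0.5 * np.abs(a / n - b / n).sum()
        assert tv < 0.05


def test_bda_path_loglik_consistency(toy, scenario1_params):
    """The complete-data density equals the sum of the factorized joint
    transition densities plus the measurement terms."""
    from txswitch.bda import bda_joint_logpdf
    from txswitch.smc import bda_path_loglik
    p = scenario1_params
    ref = initial_path(toy, p)
    ll = bda_path_loglik(ref, toy, p)
    s = p.sigma_eps
    manual = (-0.5 * math.log(2 * math.pi * s * s)
              - 0.5 * (toy.values[0] - p.P0_tilde) ** 2 / s ** 2)
    state = (p.M0, p.P0_tilde)
    for i in range(len(toy) - 1):
        new = (ref.M[i], ref.P[i])
        manual += bda_joint_logpdf(new, state, p, toy.times[i],
                                   toy.times[i + 1] - toy.times[i])
        manual += (-0.5 * math.log(2 * math.pi * s * s)
                   - 0.5 * (toy.values[i + 1] - ref.P[i]) ** 2 / s ** 2)
        state = new
    assert ll == pytest.approx(manual, rel=1e-9)
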