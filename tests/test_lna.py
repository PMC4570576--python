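import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from txswitch import _kernels
from txswitch.lna import (grid_moments, lna_transition, macroscopic_path,
                          ode_segment, simulate_lna_path)
from txswitch.model import CellParams, SwitchFunction


class TestOdeSegment:
    def test_tau_zero_identity(self, scenario1_params):
        phi0 = np.array([4.0, 9.0])
        np.testing.assert_allclose(
            ode_segment(phi0, 6.0, scenario1_params, 0.0), phi0)

    def test_closed_form_value(self, scenario1_params):
        out = ode_segment((0, 0), 6.0, scenario1_params, 1.0)
        assert out[0] == pytest.approx(6 * (1 - math.exp(-1)), rel=1e-12)

    def test_fixed_point(self, scenario1_params):
        out = ode_segment((0, 0), 6.0, scenario1_params, 200.0)
        np.testing.assert_allclose(out, [6.0, 3 * 6 / (1 * 0.7)],
                                   rtol=1e-10)

    def test_matches_numerical_integration(self, scenario1_params):
        p = scenario1_params

        def rhs(t, x):
            return [6.0 - p.delta_m * x[0],
                    p.alpha * x[0] - p.delta_p * x[1]]

        sol = solve_ivp(rhs, (0, 3.0), [2.0, 11.0], rtol=1e-12,
                        atol=1e-12)
        np.testing.assert_allclose(
            ode_segment((2, 11), 6.0, p, 3.0), sol.y[:, -1], rtol=1e-8)

    def test_negative_tau_errors(self, scenario1_params):
        with pytest.raises(ValueError):
            ode_segment((0, 0), 6.0, scenario1_params, -1.0)


class TestLnaTransition:
    def test_no_hazards_degenerate(self):
        fn = SwitchFunction.constant(1e-300, 5.0)
        pars = CellParams(fn, alpha=1e-300, delta_m=1e-300,
                          delta_p=1e-300, kappa=1, sigma_eps=1)
        tr = lna_transition((0, 0), 0.0, 1.0, pars)
        np.testing.assert_allclose(tr.mean, [0, 0], atol=1e-12)
        np.testing.assert_allclose(tr.cov, np.zeros((2, 2)), atol=1e-12)

    def test_immigration_death_stationary_poisson(self):
        """beta=6, delta_m=1: stationary mRNA variance equals the mean 6
        (the LNA is exact for the linear immigration-death marginal)."""
        fn = SwitchFunction.constant(6.0, 500.0)
        pars = CellParams(fn, alpha=1e-12, delta_m=1.0, delta_p=0.7,
                          kappa=1, sigma_eps=1, M0=6, P0=0)
        tr = lna_transition((6, 0), 0.0, 400.0, pars)
        assert tr.cov[0, 0] == pytest.approx(6.0, rel=1e-8)

    def test_stationary_protein_variance(self, constant_params):
        """Var(P) -> mean * (1 + alpha/(delta_m + delta_p)) ~ 71.09."""
        tr = lna_transition((6, 26), 0.0, 400.0, constant_params)
        mean_p = 3 * 6 / (1 * 0.7)
        expected = mean_p * (1 + 3 / 1.7)
        assert tr.cov[1, 1] == pytest.approx(expected, rel=1e-8)
        assert tr.cov[1, 1] == pytest.approx(71.09, abs=0.01)

    def test_chapman_kolmogorov(self, scenario1_params):
        """Composing transitions equals one long step (linear-Gaussian
        semigroup), including across a switch time."""
        p = scenario1_params
        x = np.array([6.0, 26.0])
        one = lna_transition(x, 10.0, 4.0, p)   # crosses the t=12 switch
        a = lna_transition(x, 10.0, 1.5, p)
        b = lna_transition(a.mean, 11.5, 2.5, p)
        np.testing.assert_allclose(b.mean, one.mean, rtol=1e-10)
        F = _kernels._expJ(p.delta_m, p.delta_p, p.alpha, 2.5)
        cov = F @ a.cov @ F.T + b.cov
        np.testing.assert_allclose(cov, one.cov, rtol=1e-10, atol=1e-10)

    def test_invalid_inputs(self, scenario1_params):
        with pytest.raises(ValueError):
            lna_transition((1, 1), 0.0, 0.0, scenario1_params)
        with pytest.raises(ValueError):
            lna_transition((-1, 1), 0.0, 1.0, scenario1_params)


class TestCovarianceTwoWays:
    def test_closed_form_vs_matrix_exponential(self):
        """The partial-fraction closed form and the augmented matrix
        exponential must agree to 1e-8."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            dm = math.exp(rng.normal(0, 0.5))
            dp = math.exp(rng.normal(-0.3, 0.5))
            at = math.exp(rng.normal(1, 0.5))
            kap = math.exp(rng.normal(0, 0.5))
            beta = math.exp(rng.normal(2, 1))
            dt = rng.uniform(0.05, 1.5)
            v = np.abs(rng.normal(0, 10, 5))
            w = np.empty(5)
            if not _kernels._prop_moments(v, w, beta, dm, dp, at, kap, dt):
                continue
            E, G = _kernels._moment_propagator(dm, dp, at, kap, dt)
            ref = E @ v + beta * G
            np.testing.assert_allclose(w, ref, rtol=1e-8, atol=1e-8)

    def test_against_ode_integration(self, scenario1_params):
        """Independent route: integrate the moment ODEs numerically."""
        p = scenario1_params
        beta, dm, dp, at, kap = 6.0, p.delta_m, p.delta_p, p.alpha, 1.0

        def rhs(t, v):
            return [beta - dm * v[0],
                    at * v[0] - dp * v[1],
                    beta + dm * v[0] - 2 * dm * v[2],
                    at * v[2] - (dm + dp) * v[3],
                    kap * (at * v[0] + dp * v[1]) + 2 * at * v[3]
                    - 2 * dp * v[4]]

        v0 = [6.0, 26.0, 0, 0, 0]
        sol = solve_ivp(rhs, (0, 0.75), v0, rtol=1e-12, atol=1e-12)
        w = np.empty(5)
        assert _kernels._prop_moments(np.array(v0, float), w, beta, dm,
                                      dp, at, kap, 0.75)
        np.testing.assert_allclose(w, sol.y[:, -1], rtol=1e-8)


class TestLnaPaths:
    def test_zero_noise_equals_ode(self):
        """With vanishing hazards the sampled path is deterministic."""
        fn = SwitchFunction.constant(1e-300, 5.0)
        pars = CellParams(fn, alpha=1e-300, delta_m=1e-300,
                          delta_p=1e-300, kappa=1, sigma_eps=1, M0=4, P0=9)
        grid = np.linspace(0, 5, 11)
        path = simulate_lna_path(pars, grid, seed=0)[0]
        np.testing.assert_allclose(path, np.tile([4.0, 9.0], (11, 1)),
                                   atol=1e-9)

    def test_means_match_ssa_high_abundance(self):
        """Scenario-2 abundances: LNA and SSA pointwise means agree."""
        from txswitch.ssa import simulate_ensemble
        fn = SwitchFunction(np.array([12.0, 20.0]),
                            np.array([20.0, 40.0, 60.0]), 42.0)
        pars = CellParams(fn, alpha=3.0, delta_m=1.0, delta_p=0.7,
                          kappa=1, sigma_eps=2, M0=20, P0=86)
        grid = np.array([0.0, 6.0, 16.0, 30.0])
        n = 2000
        ssa = simulate_ensemble(pars, grid, n, seed=1).astype(float)
        lna = simulate_lna_path(pars, grid, seed=2, n_paths=n)
        for ti in range(1, 4):
            for sp in range(2):
                se = (ssa[:, ti, sp].std(ddof=1) / math.sqrt(n)
                      + lna[:, ti, sp].std(ddof=1) / math.sqrt(n))
                diff = abs(ssa[:, ti, sp].mean() - lna[:, ti, sp].mean())
                assert diff < 3 * se

    def test_variance_not_underestimated_at_low_counts(
            self, scenario1_params):
        """At scenario-1 abundances the Gaussian LNA envelope is at least
        as wide as the exact one at low-count times."""
        from txswitch.ssa import simulate_ensemble
        grid = np.array([0.0, 25.0, 35.0])  # inside the beta=2 segment
        n = 3000
        ssa = simulate_ensemble(scenario1_params, grid, n,
                                seed=3).astype(float)
        lna = simulate_lna_path(scenario1_params, grid, seed=4, n_paths=n)
        for ti in (1, 2):
            assert (lna[:, ti, 0].var(ddof=1)
                    > 0.9 * ssa[:, ti, 0].var(ddof=1))


def test_scaled_moments_consistency(scenario1_params):
    """kappa-scaled protein moments: mean x kappa, variance x kappa^2."""
    p2 = scenario1_params.with_(kappa=2.0)
    phi1, _, Q1 = grid_moments(scenario1_params, [0.0, 1.0], scaled=False)
    phi2, _, Q2 = grid_moments(p2, [0.0, 1.0], scaled=True)
    assert phi2[1, 1] == pytest.approx(2 * phi1[1, 1], rel=1e-10)
    assert Q2[0, 1, 1] == pytest.approx(4 * Q1[0, 1, 1], rel=1e-10)
    assert Q2[0, 0, 0] == pytest.approx(Q1[0, 0, 0], rel=1e-10)


def test_macroscopic_path_handles_switches(scenario1_params):
    phi = macroscopic_path(scenario1_params, np.array([0.0, 12.0, 20.0,
                                                       42.0]))
    # stationary before the first switch, relaxing toward 20 after it
    assert phi[1, 0] == pytest.approx(6.0, rel=1e-6)
    assert 6.0 < phi[2, 0] <= 20.0
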