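import math

import numpy as np
import pytest

import txswitch.mcmc as mc
from txswitch.mcmc import (CellState, ChainState, MCMCConfig,
                           PosteriorStore, hyper_draw, mh_update_block,
                           posterior_profile, rj_update, run_chain)
from txswitch.model import HyperParams, TimeSeries
from txswitch.priors import (PriorConfig, _pk_table, log_prior_k,
                             log_prior_s, mix_logpdf, mix_logpdf_arr,
                             mix_sample)


@pytest.fixture()
def flat_state():
    """Single-cell chain state with a flat likelihood (prior sampling)."""
    pr = PriorConfig()
    grid = np.arange(0.0, 42.25, 0.25)
    y = TimeSeries(grid, np.zeros(grid.size))
    cell = CellState(np.empty(0), np.array([1.0]), 0.0, 0.0, 0.0, 0.0,
                     0.0, 0.0, 0.0)
    cell.ll = 0.0
    st = ChainState(cells=[cell], hyper=HyperParams(), priors=pr,
                    config=MCMCConfig(n_iter=1, seed=0), data=[y],
                    rng=np.random.default_rng(17))
    return st


class TestPriors:
    def test_k_prior_normalized(self):
        pr = PriorConfig()
        pk = np.exp([log_prior_k(k, pr) for k in range(pr.k_max + 1)])
        assert pk.sum() == pytest.approx(1.0, abs=1e-12)
        assert log_prior_k(-1, pr) == -np.inf
        assert log_prior_k(pr.k_max + 1, pr) == -np.inf

    def test_switch_time_prior_is_normalized_density(self):
        """p(s|k) integrates to one over the separation-constrained
        ordered region (Monte-Carlo check for k=2)."""
        pr = PriorConfig(horizon=10.0, min_sep=0.5, k_max=8)
        rng = np.random.default_rng(0)
        n = 200_000
        s = np.sort(rng.uniform(0, 10, (n, 2)), axis=1)
        edges_ok = ((s[:, 0] >= 0.5) & (10 - s[:, 1] >= 0.5)
                    & (np.diff(s, axis=1)[:, 0] >= 0.5))
        # density k!/span^k on the valid region; integral over the
        # unordered square is span^k, fraction of valid ordered draws:
        frac = edges_ok.mean()
        vol_ordered = 100 / 2 * frac       # valid ordered volume
        dens = math.exp(log_prior_s(2, pr))
        assert dens * vol_ordered == pytest.approx(1.0, abs=0.02)

    def test_mixture_density_consistency(self):
        h = HyperParams()
        xs = np.array([0.3, 2.2, -1.0])
        assert mix_logpdf_arr(xs, h) == pytest.approx(
            sum(mix_logpdf(x, h) for x in xs), rel=1e-12)

    def test_mixture_sampler_moments(self):
        h = HyperParams(beta_weights=np.array([1.0, 0.0]),
                        beta_means=np.array([2.0, 9.0]),
                        beta_vars=np.array([0.25, 1.0]))
        rng = np.random.default_rng(1)
        draws = [mix_sample(h, rng) for _ in range(2000)]
        assert np.mean(draws) == pytest.approx(2.0, abs=0.05)


class TestRJPriorRecovery:
    def test_python_updates_sample_the_k_prior(self, flat_state):
        """With a flat likelihood the RJ chain's k distribution matches
        the truncated Poisson prior (standard RJ correctness check)."""
        mc_orig = mc._loglik
        mc._loglik = lambda *a, **k: 0.0
        try:
            st = flat_state
            ks = np.empty(40_000, int)
            for i in range(ks.size):
                rj_update(st, 0)
                ks[i] = st.cells[0].k
        finally:
            mc._loglik = mc_orig
        pk = np.exp(_pk_table(st.priors))
        emp = np.bincount(ks, minlength=st.priors.k_max + 1) / ks.size
        assert 0.5 * np.abs(emp - pk).sum() < 0.05

    def test_kernel_updates_sample_the_k_prior(self, degradation_priors):
        """The fused kernel path must agree with the same prior."""
        grid = np.arange(0.0, 42.25, 0.25)
        y = TimeSeries(grid, np.zeros(grid.size))
        conf = MCMCConfig(method="lna", n_iter=40_000, seed=5, thin=1,
                          flat_likelihood=True, update_hypers=False)
        store = run_chain([y], degradation_priors, conf)
        pk = np.exp(_pk_table(degradation_priors))
        emp = np.bincount(store.k[0],
                          minlength=degradation_priors.k_max + 1)
        emp = emp / emp.sum()
        assert 0.5 * np.abs(emp - pk).sum() < 0.05

    def test_delete_at_k0_always_rejected(self, flat_state):
        """From k=0 only the add move can change the configuration."""
        st = flat_state
        for _ in range(200):
            rj_update(st, 0)
            if st.cells[0].k:
                break
        # force k=0 and check deletes are no-ops by exhausting moves
        st.cells[0].s = np.empty(0)
        st.cells[0].lb = np.array([1.0])
        mc_orig = mc._loglik
        mc._loglik = lambda *a, **k: 0.0
        try:
            for _ in range(100):
                rj_update(st, 0)
                assert st.cells[0].k >= 0
        finally:
            mc._loglik = mc_orig


class TestMHBlocks:
    def test_flat_likelihood_block_samples_prior(self, flat_state):
        """With a flat likelihood block 2 samples the (Gaussian) prior of
        log alpha~ - log kappa: chain mean/sd match within 3 SE."""
        mc_orig = mc._loglik
        mc._loglik = lambda *a, **k: 0.0
        try:
            st = flat_state
            st.adapt = [(mc._DiagAdapt(), mc._BlockAdapt(4))]
            vals = np.empty(30_000)
            for i in range(vals.size):
                st.iteration = i
                mh_update_block(st, 0, 2)
                vals[i] = st.cells[0].lat - st.cells[0].lkap
        finally:
            mc._loglik = mc_orig
        h = st.hyper
        # generous tolerance: strongly autocorrelated chain
        assert abs(vals[5000:].mean() - h.mu_alpha) < 0.15
        assert abs(vals[5000:].std() - math.sqrt(h.var_alpha)) < 0.2

    def test_rejection_outside_bounds(self, flat_state):
        st = flat_state
        st.adapt = [(mc._DiagAdapt(), mc._BlockAdapt(4))]
        st.cells[0].lat = 19.999
        mc_orig = mc._loglik
        mc._loglik = lambda *a, **k: 0.0
        try:
            for i in range(500):
                st.iteration = i
                mh_update_block(st, 0, 2)
                assert abs(st.cells[0].lat) <= st.priors.log_bound
        finally:
            mc._loglik = mc_orig


class TestHyperUpdate:
    def test_no_data_samples_hyper_prior(self):
        pr = PriorConfig()
        rng = np.random.default_rng(3)
        h = HyperParams()
        mus = []
        for _ in range(4000):
            hyper_draw(h, pr, rng, np.empty(0), np.empty(0), np.empty(0),
                       np.empty(0))
            mus.append(h.mu_alpha)
        # prior: mu | var ~ N(m, var/k0), var ~ IG(a, b) with m=0
        assert abs(np.mean(mus)) < 0.5
        assert np.std(mus) > 1.0  # k0=0.01 makes the prior wide

    def test_degenerate_data_concentrates(self):
        pr = PriorConfig()
        rng = np.random.default_rng(4)
        h = HyperParams()
        la = np.full(200, 1.234)
        for _ in range(200):
            hyper_draw(h, pr, rng, la, np.empty(0), np.empty(0),
                       np.empty(0))
        assert h.mu_alpha == pytest.approx(1.234, abs=0.05)

    def test_single_component_data_collapses_mixture(self):
        """Rates from one log-normal: the two-component fit drives one
        weight very low."""
        pr = PriorConfig()
        rng = np.random.default_rng(5)
        rates = rng.normal(2.0, 0.5, 40)
        h = HyperParams()
        minw = []
        for it in range(2000):
            hyper_draw(h, pr, rng, np.empty(0), np.empty(0), np.empty(0),
                       rates)
            if it >= 500:
                minw.append(h.beta_weights.min())
        assert np.mean(minw) < 0.1


class TestPosteriorProfile:
    @staticmethod
    def _store(k, s_list, lb_list):
        n = len(k)
        return PosteriorStore(
            method="lna", n_iter=n, thin=1, cell_ids=["c0"],
            k=[np.array(k)], switch_times=[s_list], log_rates=[lb_list],
            params=[np.zeros((n, 7))], hyper=np.zeros((n, 12)),
            accept={})

    def test_identical_samples(self):
        s = [np.array([10.0])] * 4
        lb = [np.log([2.0, 5.0])] * 4
        store = self._store([1] * 4, s, lb)
        prof = posterior_profile(store, [5.0, 15.0], burn_frac=0.0)
        np.testing.assert_allclose(prof[0], [2.0, 5.0])

    def test_median_of_two_constant_samples(self):
        s = [np.empty(0), np.empty(0)]
        lb = [np.log([4.0]), np.log([6.0])]
        store = self._store([0, 0], s, lb)
        prof = posterior_profile(store, [1.0, 30.0], burn_frac=0.0)
        np.testing.assert_allclose(prof[0], [5.0, 5.0])

    def test_empty_store_errors(self):
        store = self._store([], [], [])
        with pytest.raises(ValueError):
            posterior_profile(store, [1.0])

    def test_mixture_relabeling_leaves_profile_unchanged(self):
        """Swapping component labels permutes hyper draws but cannot
        change the rate profile, which is label-free."""
        s = [np.array([10.0])] * 4
        lb = [np.log([2.0, 5.0])] * 4
        store = self._store([1] * 4, s, lb)
        prof1 = posterior_profile(store, [5.0, 15.0], burn_frac=0.0)
        store.hyper = store.hyper[:, [0, 1, 2, 3, 4, 5, 9, 10, 11, 6, 7, 8]]
        prof2 = posterior_profile(store, [5.0, 15.0], burn_frac=0.0)
        np.testing.assert_array_equal(prof1, prof2)


class TestRunChain:
    def test_smoke_contract(self, degradation_priors):
        """Single cell, LNA: runs to completion with acceptance rates in
        (0, 1) and a store of the right shape."""
        from txswitch.synthetic import generate_dataset
        data, _ = generate_dataset(1, preset="scenario1", seed=1)
        conf = MCMCConfig(method="lna", n_iter=3000, seed=2)
        store = run_chain(data, degradation_priors, conf)
        for key in ("rj", "block1", "block2"):
            assert 0 < store.accept[key][0] < 1
        assert store.n_draws == 3000 // store.thin
        assert store.params[0].shape[1] == 7

    def test_kappa_fixed_mode_keeps_kappa(self, degradation_priors):
        from txswitch.synthetic import generate_dataset
        data, _ = generate_dataset(1, preset="scenario1", seed=1)
        conf = MCMCConfig(method="lna", n_iter=500, seed=2,
                          kappa_mode="fixed",
                          kappa_values=np.array([1.7]))
        store = run_chain(data, degradation_priors, conf)
        np.testing.assert_allclose(store.params[0][:, 3], math.log(1.7))

    def test_bda_smoke(self, degradation_priors):
        from txswitch.synthetic import generate_dataset
        data, _ = generate_dataset(1, preset="scenario1", seed=1)
        conf = MCMCConfig(method="bda", n_iter=300, seed=2,
                          n_particles=30)
        store = run_chain(data, degradation_priors, conf)
        assert store.n_draws > 0

    def test_input_validation(self, degradation_priors):
        with pytest.raises(ValueError):
            run_chain([], degradation_priors, MCMCConfig())
        a = TimeSeries(np.array([0.0, 1.0]), np.zeros(2))
        b = TimeSeries(np.array([5.0, 6.0]), np.zeros(2))
        with pytest.raises(ValueError, match="overlap"):
            run_chain([a, b], degradation_priors, MCMCConfig())
        with pytest.raises(ValueError):
            run_chain([a], degradation_priors,
                      MCMCConfig(kappa_mode="fixed"))
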