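import numpy as np
import pytest

from jointabund.estimators import BayesianAbundanceEstimator
from jointabund.inference import McmcConfig, fit, gelman_rubin, initialize_chains
from jointabund.model import ModelSpec, UnconstrainedPosterior
from jointabund.nuts import sample_chain
from jointabund.simulate import SimulationConfig, simulate_paired

from conftest import make_paired


class TestGelmanRubin:
    def test_same_distribution_near_one(self, rng):
        x = rng.standard_normal((2, 10_000))
        assert 0.99 <= gelman_rubin(x) <= 1.01

    def test_separated_chains_inflate(self, rng):
        x = rng.standard_normal((2, 500))
        x[1] += 10
        assert gelman_rubin(x) > 1.5

    def test_constant_chains_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = gelman_rubin(np.ones((2, 50)))
        assert np.isnan(out)

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestNutsSampler:
    def test_recovers_gaussian_moments(self, rng):
        cov = np.diag([1.0, 4.0, 0.25])
        prec = np.linalg.inv(cov)

        def lg(th):
            return -0.5 * th @ prec @ th, -prec @ th

        res = sample_chain(lg, np.zeros(3), 400, 2500, rng)
        np.testing.assert_allclose(res.draws.mean(0), 0.0, atol=0.15)
        np.testing.assert_allclose(res.draws.var(0), np.diag(cov), rtol=0.2)

    def test_same_seed_reproduces_draws(self):
        def lg(th):
            return -0.5 * float(th @ th), -th

        a = sample_chain(lg, np.ones(4), 100, 200, np.random.default_rng(3))
        b = sample_chain(lg, np.ones(4), 100, 200, np.random.default_rng(3))
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_nonfinite_start_rejected(self):
        def lg(th):
            return -np.inf, np.zeros_like(th)

        with pytest.raises(ValueError, match="non-finite"):
            sample_chain(lg, np.zeros(2), 10, 10, np.random.default_rng(0))


class TestInitialization:
    def test_anchor_reproduces_naive_estimate(self, tiny_paired):
        from jointabund.naive import NaiveScalingEstimator

        spec = ModelSpec()
        mcmc = McmcConfig(chains=1, init_strategy="naive_anchor", warmup_iters=10,
                          total_iters=20)
        theta = initialize_chains(tiny_paired, spec, mcmc)[0]
        post = UnconstrainedPosterior(tiny_paired, spec)
        z_mu = post.unpack(theta)["z_mu"]
        naive = NaiveScalingEstimator().fit(tiny_paired.W, tiny_paired.V)
        np.testing.assert_allclose(z_mu, np.log(naive.mu_hat_ + 0.5), atol=1e-9)

    def test_zero_count_taxon_gets_pseudocount(self):
        data = make_paired([[10, 20, 0], [5, 10, 0]], [[10, 20], [5, 10]])
        spec = ModelSpec()
        mcmc = McmcConfig(chains=1, init_strategy="naive_anchor", warmup_iters=10,
                          total_iters=20)
        theta = initialize_chains(data, spec, mcmc)[0]
        z_mu = UnconstrainedPosterior(data, spec).unpack(theta)["z_mu"]
        s = np.array([30 / 30, 15 / 15])
        np.testing.assert_allclose(z_mu[:, 2], np.log(0.5 * s), atol=1e-9)

    def test_random_strategy_gives_distinct_chains(self, tiny_paired):
        mcmc = McmcConfig(chains=3, init_strategy="random", warmup_iters=10,
                          total_iters=20)
        inits = initialize_chains(tiny_paired, ModelSpec(), mcmc)
        assert not np.allclose(inits[0], inits[1])
        assert not np.allclose(inits[1], inits[2])

    def test_sample_with_no_observed_reads_uses_global_scaling(self, caplog):
        data = make_paired([[5, 5, 1], [0, 0, 3]], [[7, 3], [2, 2]])
        mcmc = McmcConfig(chains=1, init_strategy="naive_anchor", warmup_iters=10,
                          total_iters=20)
        with caplog.at_level("WARNING"):
            theta = initialize_chains(data, ModelSpec(), mcmc)[0]
        assert np.all(np.isfinite(theta))
        assert "global scaling" in caplog.text


class TestFit:
    def test_same_seed_gives_identical_draws(self):
        data = make_paired(
            [[50, 30, 10], [40, 20, 5], [60, 35, 12], [45, 25, 8], [55, 28, 9]],
            [[45, 25], [38, 18], [66, 30], [41, 27], [52, 31]],
        )
        mcmc = McmcConfig(chains=2, warmup_iters=120, total_iters=220, seed=9)
        d1, _ = fit(data, ModelSpec(), mcmc)
        d2, _ = fit(data, ModelSpec(), mcmc)
        np.testing.assert_array_equal(d1.mu, d2.mu)
        np.testing.assert_array_equal(d1.e, d2.e)

    def test_recovery_and_convergence(self, recovery_fit):
        """Posterior means track the truth and chains mix."""
        est = recovery_fit["est"]
        mu_true = recovery_fit["mu_true"]
        draws = est.draws_
        sd = draws.mu.std(axis=0)
        within = np.abs(est.mu_mean_ - mu_true) <= 3 * np.maximum(sd, 1e-12)
        assert within.mean() >= 0.90
        assert est.diagnostics_.mu_rhat_median < 1.05

    def test_posterior_tracks_observed_concentrations(self, recovery_fit):
        """Regression of posterior-mean mu on observed V has slope near 1."""
        est = recovery_fit["est"]
        paired = recovery_fit["paired"]
        qobs = paired.qobs
        x = paired.V.ravel().astype(float)
        y = est.mu_mean_[:, :qobs].ravel()
        keep = x > 50  # avoid zero-dominated cells
        slope = np.polyfit(x[keep], y[keep], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_soft_centering_keeps_log_efficiencies_near_zero(self, recovery_fit):
        est = recovery_fit["est"]
        mean_log_e = np.log(est.draws_.e).mean(axis=1)
        assert abs(mean_log_e.mean()) < 0.5

    def test_efficiency_naive_convergence(self):
        """Equal-efficiency fit on equal-efficiency data mixes cleanly."""
        cfg = SimulationConfig(q=10, qobs=5, n=30, sigma_e=0.0, seed=0)
        truth, paired, mu_true, _ = simulate_paired(cfg)
        est = BayesianAbundanceEstimator(
            variant="efficiency_naive", chains=2, warmup=300, iters=500, seed=4
        ).fit(paired)
        assert est.diagnostics_.mu_rhat_median < 1.05

    def test_hard_centering_transforms_draws(self):
        data = make_paired(
            [[50, 30, 10], [40, 20, 5], [60, 35, 12], [45, 25, 8]],
            [[45, 25], [38, 18], [66, 30], [41, 27]],
        )
        mcmc = McmcConfig(chains=2, warmup_iters=120, total_iters=230, seed=9)
        draws, _ = fit(data, ModelSpec(centering="hard_observed"), mcmc)
        log_gm = np.log(draws.e[:, :2]).mean(axis=1)
        np.testing.assert_allclose(log_gm, 0.0, atol=1e-10)

    def test_estimator_exposes_sklearn_interface(self, recovery_fit):
        est = recovery_fit["est"]
        params = est.get_params()
        assert params["variant"] == "varying_efficiency"
        assert est.predict().shape == est.mu_mean_.shape
        clone_params = BayesianAbundanceEstimator(**params).get_params()
        assert clone_params == params
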