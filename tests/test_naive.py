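import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from jointabund.naive import (
    NaiveScalingEstimator,
    UndefinedScalingError,
    naive_confidence_interval,
    naive_log_variance,
    naive_point,
    naive_prediction_interval,
    scaling_factor,
)


class TestScalingFactor:
    def test_worked_example(self):
        assert scaling_factor([10, 20], [5, 10]) == 2.0

    def test_identity_when_tables_agree(self):
        assert scaling_factor([3, 7], [3, 7]) == 1.0

    def test_zero_observed_reads_errors(self):
        with pytest.raises(UndefinedScalingError, match="sample 3"):
            scaling_factor([1, 2], [0, 0], sample_id=3)

    @given(c=st.floats(0.1, 50))
    def test_scale_equivariance(self, c):
        base = scaling_factor([10, 20], [5, 10])
        assert np.isclose(scaling_factor([10 * c, 20 * c], [5, 10]), c * base)


class TestNaivePoint:
    def test_elementwise_product(self):
        assert naive_point(2.0, [5, 10, 15]).tolist() == [10, 20, 30]

    def test_zeros_preserved(self):
        assert naive_point(3.0, [0, 0]).tolist() == [0, 0]

    def test_unit_factor_is_identity(self):
        assert naive_point(1.0, [4, 5]).tolist() == [4, 5]


class TestLogVariance:
    def test_worked_example_observed_taxon(self):
        # T_V = 100, W_ij = 50 (observed), T_W = 200
        v = naive_log_variance([100], [150, 50, 7], qobs=2, j=1)
        assert v == pytest.approx(0.01 + 0.02 - 0.005, abs=1e-12)

    def test_unobserved_taxon_adds_total_term(self):
        v = naive_log_variance([100], [150, 50, 40], qobs=2, j=2)
        assert v == pytest.approx(1 / 100 + 1 / 40 + 1 / 200, abs=1e-12)

    def test_zero_count_is_missing(self):
        assert np.isnan(naive_log_variance([10], [5, 0], qobs=1, j=1))

    @given(data=st.data())
    def test_variance_nonnegative(self, data):
        # for observed taxa W_ij <= T_W, so 1/W_ij - 1/T_W >= 0; for
        # unobserved taxa every term is positive
        qobs = data.draw(st.integers(1, 4))
        q = data.draw(st.integers(qobs, 6))
        W = data.draw(
            st.lists(st.integers(0, 1000), min_size=q, max_size=q).filter(
                lambda w: sum(w[:qobs]) > 0
            )
        )
        V = data.draw(st.lists(st.integers(0, 1000), min_size=qobs, max_size=qobs)
                      .filter(lambda v: sum(v) > 0))
        j = data.draw(st.integers(0, q - 1))
        v = naive_log_variance(V, W, qobs, j)
        assert np.isnan(v) or v >= 0.0

    def test_matches_parametric_bootstrap_small(self, rng):
        """Plug-in delta-method variance vs a 40k-resample bootstrap."""
        qobs, q, M = 3, 5, 50_000
        p = np.array([0.3, 0.25, 0.2, 0.15, 0.1])
        W = rng.multinomial(M, p)
        V = rng.integers(200, 2000, size=qobs)
        B = 40_000
        tv = rng.poisson(V.sum(), size=B).astype(float)
        Wb = rng.multinomial(M, W / M, size=B).astype(float)
        for j in (1, 4):  # one observed, one unobserved taxon
            tw = Wb[:, :qobs].sum(axis=1)
            ok = (Wb[:, j] > 0) & (tw > 0) & (tv > 0)
            emp = np.var(np.log(tv[ok]) + np.log(Wb[ok, j]) - np.log(tw[ok]))
            formula = naive_log_variance(V, W, qobs, j)
            assert formula == pytest.approx(emp, rel=0.15)


class TestIntervals:
    def test_zero_variance_degenerates_to_point(self):
        lo, hi = naive_confidence_interval(10.0, 0.0, 0.05)
        assert lo == hi == pytest.approx(10.0)

    def test_confidence_worked_example(self):
        lo, hi = naive_confidence_interval(10.0, 0.025, 0.05)
        assert (round(lo, 3), round(hi, 3)) == (7.335, 13.633)

    def test_prediction_adds_poisson_noise_term(self):
        mu, v, a = 10.0, 0.025, 0.05
        lo, hi = naive_prediction_interval(mu, v, a)
        z = stats.norm.ppf(1 - a / 2)
        half = z * np.sqrt(1 / mu + v)
        assert lo == pytest.approx(mu * np.exp(-half))
        assert hi == pytest.approx(mu * np.exp(half))

    def test_prediction_contains_confidence(self):
        ci = naive_confidence_interval(7.0, 0.04)
        pi = naive_prediction_interval(7.0, 0.04)
        assert pi[0] < ci[0] and ci[1] < pi[1]

    def test_zero_estimate_has_no_interval(self):
        assert naive_confidence_interval(0.0, 0.1) is None
        assert naive_prediction_interval(0.0, 0.1) is None

    @given(v1=st.floats(0.001, 1), v2=st.floats(0.001, 1))
    def test_width_monotone_in_variance(self, v1, v2):
        if v1 > v2:
            v1, v2 = v2, v1
        lo1, hi1 = naive_confidence_interval(5.0, v1)
        lo2, hi2 = naive_confidence_interval(5.0, v2)
        assert hi2 - lo2 >= hi1 - lo1


class TestEstimator:
    def test_fitted_attributes(self, tiny_paired):
        est = NaiveScalingEstimator().fit(tiny_paired.W, tiny_paired.V)
        n, q = tiny_paired.W.shape
        assert est.s_hat_.shape == (n,)
        assert est.mu_hat_.shape == (n, q)
        # zeros in W produce zero estimates and missing variances
        zero = tiny_paired.W == 0
        assert (est.mu_hat_[zero] == 0).all()
        assert np.isnan(est.var_log_mu_hat_[zero]).all()

    def test_subcomposition_total_preserved(self, tiny_paired):
        """Estimated totals over observed taxa equal observed totals."""
        est = NaiveScalingEstimator().fit(tiny_paired.W, tiny_paired.V)
        qobs = tiny_paired.qobs
        np.testing.assert_allclose(
            est.mu_hat_[:, :qobs].sum(axis=1), tiny_paired.V.sum(axis=1)
        )

    def test_doubling_concentrations_doubles_estimates(self, tiny_paired):
        a = NaiveScalingEstimator().fit(tiny_paired.W, tiny_paired.V)
        b = NaiveScalingEstimator().fit(tiny_paired.W, 2 * tiny_paired.V)
        np.testing.assert_allclose(b.mu_hat_, 2 * a.mu_hat_)

    def test_sklearn_params_roundtrip(self):
        est = NaiveScalingEstimator(alpha=0.1)
        assert est.get_params() == {"alpha": 0.1}
        est.set_params(alpha=0.2)
        assert est.alpha == 0.2

    def test_interval_coverage_on_equal_efficiency_data(self):
        """~95% CI coverage for observed taxa on moderate-abundance data."""
        from jointabund.simulate import SimulationConfig, simulate_paired

        hits, total = 0, 0
        beta_rng = np.random.default_rng(42)
        for rep in range(8):
            cfg = SimulationConfig(q=8, qobs=4, n=40, sigma_e=0.0, seed=100 + rep)
            beta = beta_rng.uniform(2.0, 6.0, size=8)  # all taxa comfortably abundant
            truth, paired, mu_true, _ = simulate_paired(cfg, beta=beta)
            est = NaiveScalingEstimator().fit(paired.W, paired.V)
            lo, hi = est.confidence_intervals()
            qobs = paired.qobs
            keep = est.mu_hat_[:, :qobs] > 0
            inside = (lo[:, :qobs] <= mu_true[:, :qobs]) & (
                mu_true[:, :qobs] <= hi[:, :qobs]
            )
            hits += inside[keep].sum()
            total += keep.sum()
        assert 0.90 <= hits / total <= 0.99
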