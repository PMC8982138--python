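import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from jointabund.data import CovariateDesign
from jointabund.model import (
    Hyperparameters,
    LatentState,
    ModelSpec,
    UnconstrainedPosterior,
    covariate_mean,
    hard_center,
    log_joint_density,
    relative_abundance_probs,
)

from conftest import make_paired


def random_state(data, rng, covariate=False):
    n, q = data.W.shape
    beta = rng.normal(0, 1, size=(2, q) if covariate else q)
    return LatentState(
        mu=np.exp(rng.normal(1, 1, size=(n, q))),
        e=np.exp(rng.normal(0, 0.5, size=q)),
        beta=beta,
        Sigma_diag=np.exp(rng.normal(0, 0.3, size=q)),
        sigma_e_sq=float(np.exp(rng.normal(0, 0.3))),
    )


class TestRelativeAbundanceProbs:
    def test_equal_efficiency_reduces_to_composition(self):
        np.testing.assert_allclose(
            relative_abundance_probs([2, 3, 5], [1, 1, 1]), [0.2, 0.3, 0.5]
        )

    def test_worked_example(self):
        np.testing.assert_allclose(
            relative_abundance_probs([1, 1], [1, 3]), [0.25, 0.75]
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance_probs([1, 0], [1, 1])

    @given(c=st.floats(1e-3, 1e3))
    def test_efficiency_scale_invariance(self, c):
        mu = np.array([0.5, 2.0, 7.0])
        e = np.array([0.3, 1.0, 4.0])
        np.testing.assert_allclose(
            relative_abundance_probs(mu, c * e),
            relative_abundance_probs(mu, e),
            rtol=1e-10,
        )

    def test_rows_sum_to_one(self, rng):
        mu = np.exp(rng.normal(0, 3, size=(20, 9)))
        e = np.exp(rng.normal(0, 1, size=9))
        p = relative_abundance_probs(mu, e)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestHardCenter:
    def test_geometric_mean_removed(self):
        np.testing.assert_allclose(hard_center([2.0, 8.0], [0, 1]), [0.5, 2.0])

    def test_equal_efficiencies_become_one(self):
        np.testing.assert_allclose(hard_center([3.0, 3.0, 3.0], [0, 1, 2]), 1.0)

    def test_projection_is_idempotent(self, rng):
        e = np.exp(rng.normal(0, 1, size=6))
        once = hard_center(e, [0, 1, 2])
        twice = hard_center(once, [0, 1, 2])
        np.testing.assert_allclose(once, twice, rtol=1e-12)
        assert np.isclose(np.log(once[:3]).mean(), 0.0, atol=1e-12)


class TestCovariateMean:
    def test_zero_covariate_returns_intercept(self):
        np.testing.assert_allclose(covariate_mean([1.0, 2.0], [3.0, 4.0], 0.0), [1, 2])

    def test_worked_example(self):
        np.testing.assert_allclose(covariate_mean([0, 1], [2, -1], 1.0), [2, 0])

    def test_linear_in_covariate(self):
        b0, b1 = np.array([1.0, 2.0]), np.array([0.5, -0.5])
        m1 = covariate_mean(b0, b1, 1.0)
        m2 = covariate_mean(b0, b1, 2.0)
        np.testing.assert_allclose(m2 - m1, b1)


class TestLogJointDensity:
    def test_single_taxon_degenerates_to_poisson(self):
        data = make_paired([[3]], [[3]])
        state = LatentState(
            mu=[[2.5]], e=[1.0], beta=[0.0], Sigma_diag=[1.0], sigma_e_sq=1.0
        )
        parts = log_joint_density(
            state, data, ModelSpec(variant="efficiency_naive"), components=True
        )
        assert parts["multinomial_W"] == pytest.approx(0.0, abs=1e-12)
        assert parts["poisson_V"] == pytest.approx(
            stats.poisson.logpmf(3, 2.5), abs=1e-10
        )

    def test_matches_independent_component_densities(self, rng):
        """Joint density equals the sum of scipy per-component log-densities."""
        data = make_paired(rng.integers(0, 50, size=(2, 3)), rng.integers(0, 9, (2, 2)))
        spec = ModelSpec()
        state = random_state(data, rng)
        hyper = spec.hyper
        p = relative_abundance_probs(state.mu, state.e)
        expected = (
            stats.poisson.logpmf(data.V, state.mu[:, :2]).sum()
            + sum(
                stats.multinomial.logpmf(data.W[i], data.M[i], p[i])
                for i in range(2)
            )
            + stats.norm.logpdf(
                np.log(state.mu), state.beta[None, :], np.sqrt(state.Sigma_diag)
            ).sum()
            + stats.norm.logpdf(state.beta, 0, np.sqrt(hyper.sigma_beta_sq)).sum()
            + stats.lognorm.logpdf(
                state.Sigma_diag, np.sqrt(hyper.sigma_Sigma_sq)
            ).sum()
            + stats.lognorm.logpdf(state.e, np.sqrt(state.sigma_e_sq)).sum()
            + stats.invgamma.logpdf(
                state.sigma_e_sq, hyper.alpha_sigma, scale=hyper.kappa_sigma
            )
        )
        assert log_joint_density(state, data, spec) == pytest.approx(
            expected, abs=1e-10
        )

    def test_efficiency_scaling_touches_only_prior_term(self, rng):
        data = make_paired(rng.integers(0, 50, size=(3, 4)), rng.integers(0, 9, (3, 2)))
        spec = ModelSpec()
        state = random_state(data, rng)
        scaled = LatentState(
            mu=state.mu,
            e=state.e * 1.7,
            beta=state.beta,
            Sigma_diag=state.Sigma_diag,
            sigma_e_sq=state.sigma_e_sq,
        )
        a = log_joint_density(state, data, spec, components=True)
        b = log_joint_density(scaled, data, spec, components=True)
        for key in ("poisson_V", "multinomial_W", "mu_prior", "beta_prior", "Sigma_prior"):
            assert a[key] == pytest.approx(b[key], abs=1e-9)
        assert a["efficiency_prior"] != pytest.approx(b["efficiency_prior"])

    def test_unit_efficiency_reduction_to_efficiency_naive(self, rng):
        """Dropping the efficiency prior from the full model at e = 1
        reproduces the equal-efficiency model exactly."""
        data = make_paired(rng.integers(0, 80, size=(3, 4)), rng.integers(0, 9, (3, 2)))
        state = random_state(data, rng)
        unit = LatentState(
            mu=state.mu,
            e=np.ones(4),
            beta=state.beta,
            Sigma_diag=state.Sigma_diag,
            sigma_e_sq=state.sigma_e_sq,
        )
        full = log_joint_density(unit, data, ModelSpec(), components=True)
        naive = log_joint_density(
            unit, data, ModelSpec(variant="efficiency_naive")
        )
        reduced = sum(v for k, v in full.items() if k != "efficiency_prior")
        assert reduced == pytest.approx(naive, abs=1e-10)


class TestUnconstrainedPosterior:
    @pytest.mark.parametrize("variant", ["varying_efficiency", "efficiency_naive"])
    @pytest.mark.parametrize("covariate", [False, True])
    def test_gradient_matches_finite_differences(self, rng, variant, covariate):
        W = rng.integers(0, 200, size=(4, 3))
        W[:, 0] += 1
        cov = CovariateDesign(rng.integers(0, 2, size=4).astype(float)) if covariate else None
        data = make_paired(W, rng.integers(1, 50, (4, 2)), cov)
        spec = ModelSpec(variant=variant, covariate_adjusted=covariate)
        post = UnconstrainedPosterior(data, spec)
        theta = 0.4 * rng.standard_normal(post.dim)
        _, g = post.logp_grad(theta)
        eps = 1e-6
        for k in range(0, post.dim, 3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert g[k] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_fast_path_matches_reference(self, rng):
        W = rng.integers(0, 300, size=(6, 5))
        W[:, 0] += 1
        data = make_paired(W, rng.integers(0, 60, (6, 3)))
        for variant in ("varying_efficiency", "efficiency_naive"):
            post = UnconstrainedPosterior(data, ModelSpec(variant=variant))
            for _ in range(5):
                theta = 0.5 * rng.standard_normal(post.dim)
                l_fast, g_fast = post.logp_grad(theta)
                l_ref, g_ref = post._logp_grad_numpy(theta)
                assert l_fast == pytest.approx(l_ref, rel=1e-12)
                np.testing.assert_allclose(g_fast, g_ref, rtol=1e-9, atol=1e-9)

    def test_density_invariant_to_parameterization_devices(self, rng):
        """The sampled density differs from the plain joint density only by
        the (theta-dependent) change-of-variables terms."""
        W = rng.integers(0, 200, size=(4, 3))
        W[:, 0] += 1
        data = make_paired(W, rng.integers(1, 50, (4, 2)))
        spec = ModelSpec()
        post = UnconstrainedPosterior(data, spec)
        nc_count = (~post.center_mu).sum(axis=0)
        nc_e = (~post.obs_taxon).sum()

        def offset(theta):
            u = post.unpack(theta)
            lj = log_joint_density(post.state(theta), data, spec)
            jac = u["z_sig"].sum() + 0.5 * (nc_count * u["z_sig"]).sum()
            jac += u["z_se"] + u["z_e"].sum() + 0.5 * nc_e * u["z_se"]
            return post.logp_grad(theta)[0] - (lj + jac)

        offs = [offset(0.3 * rng.standard_normal(post.dim)) for _ in range(4)]
        np.testing.assert_allclose(offs, offs[0], atol=1e-9)

    def test_pack_unpack_roundtrip(self, rng):
        data = make_paired(rng.integers(1, 200, size=(3, 4)), rng.integers(1, 50, (3, 2)))
        post = UnconstrainedPosterior(data, ModelSpec())
        theta = rng.standard_normal(post.dim)
        u = post.unpack(theta)
        theta2 = post.pack(u["z_mu"], u["beta"], u["z_sig"], u["z_e"], u["z_se"])
        np.testing.assert_allclose(theta, theta2, atol=1e-12)


class TestValidation:
    def test_hyperparameters_must_be_positive(self):
        with pytest.raises(ValueError):
            Hyperparameters(sigma_beta_sq=-1)
        with pytest.raises(ValueError):
            Hyperparameters(alpha_level=1.5)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(variant="something_else")

    def test_latent_state_positivity(self):
        with pytest.raises(ValueError):
            LatentState(mu=[[0.0]], e=[1.0], beta=[0.0], Sigma_diag=[1.0])
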