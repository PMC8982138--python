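"""Joint hierarchical model for read counts and observed concentrations.

Data model, for sample i and taxon j:

    V_ij | mu_ij           ~ Poisson(mu_ij)                (j <= qobs)
    W_i. | M_i, mu_i., e   ~ Multinomial(M_i, p_i.),
                             p_ij = mu_ij e_j / sum_l mu_il e_l

where e_j is the detection efficiency of taxon j in the sequencing assay
relative to the concentration assay.  Priors:

    log mu_i. ~ N_q(beta, Sigma)   (or N_q(beta0 + beta1 x_i, Sigma))
    beta_j    ~ N(0, sigma_beta^2)           (iid over taxa)
    Sigma_jj  ~ Lognormal(0, sigma_Sigma^2)  (diagonal Sigma)
    e_j       ~ Lognormal(0, sigma_e^2),  sigma_e^2 ~ InvGamma(a_sigma, k_sigma)

Lognormal(0, s^2) means the *log* has variance s^2.  InvGamma uses the
shape-scale density proportional to x^(-a-1) exp(-k/x).  The zero-mean
prior on log e soft-centers the efficiencies, which are otherwise only
identified up to a multiplicative constant; hard-centering variants divide
by a geometric mean instead.  The efficiency-naive variant fixes e_j = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Hyperparameters",
    "ModelSpec",
    "LatentState",
    "relative_abundance_probs",
    "hard_center",
    "covariate_mean",
    "log_joint_density",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters.

    Defaults follow the simulation-study settings: variances of 50 for the
    taxon-level mean and log-variance priors (appropriate when the log
    concentrations themselves have variance near 50 — rescale for data on
    other scales), and a diffuse-but-proper InvGamma(2, 1) on sigma_e^2.
    The covariate-model intercept/slope prior sds default to 1.62 and 1.
    """

    sigma_beta_sq: float = 50.0
    sigma_Sigma_sq: float = 50.0
    alpha_sigma: float = 2.0
    kappa_sigma: float = 1.0
    sigma_beta0_sq: float = 1.62**2
    sigma_beta1_sq: float = 1.0
    alpha_level: float = 0.05

    def __post_init__(self):
        for name in (
            "sigma_beta_sq",
            "sigma_Sigma_sq",
            "alpha_sigma",
            "kappa_sigma",
            "sigma_beta0_sq",
            "sigma_beta1_sq",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")


_VARIANTS = ("varying_efficiency", "efficiency_naive")
_CENTERINGS = ("soft", "hard_observed", "hard_all")


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and with which priors.

    ``efficiency_naive`` fixes e_j = 1 for all j (and ignores the
    InvGamma hyperparameters); ``centering`` selects how efficiencies are
    identified under ``varying_efficiency``.  Hard centering is applied to
    posterior draws as a deterministic transform; sampling always happens
    on the raw (soft-centered) scale.
    """

    variant: str = "varying_efficiency"
    covariate_adjusted: bool = False
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    centering: str = "soft"

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.centering not in _CENTERINGS:
            raise ValueError(f"centering must be one of {_CENTERINGS}")


@dataclass(frozen=True)
class LatentState:
    """One configuration of all latent quantities.

    ``beta`` holds the taxon-level prior means (length q), or the stacked
    (beta0, beta1) pair (shape (2, q)) in the covariate-adjusted model.
    """

    mu: np.ndarray
    e: np.ndarray
    beta: np.ndarray
    Sigma_diag: np.ndarray
    sigma_e_sq: float = 1.0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        e = np.asarray(self.e, dtype=float)
        Sigma = np.asarray(self.Sigma_diag, dtype=float)
        if (mu <= 0).any():
            raise ValueError("mu must be strictly positive")
        if (e <= 0).any():
            raise ValueError("efficiencies must be strictly positive")
        if (Sigma <= 0).any():
            raise ValueError("Sigma_diag must be strictly positive")
        if self.sigma_e_sq <= 0:
            raise ValueError("sigma_e_sq must be strictly positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "Sigma_diag", Sigma)


def relative_abundance_probs(mu, e) -> np.ndarray:
    """Multinomial cell probabilities ``p_ij = mu_ij e_j / sum_l mu_il e_l``.

    Accepts a single row (length q) or an (n, q) matrix of concentrations.
    Invariant under rescaling of ``e`` by any positive constant.
    """
    mu = np.asarray(mu, dtype=float)
    e = np.asarray(e, dtype=float)
    if (mu <= 0).any() or (e <= 0).any():
        raise ValueError("mu and e must be strictly positive")
    w = mu * e
    return w / w.sum(axis=-1, keepdims=True)


def hard_center(e_raw, index_set) -> np.ndarray:
    """Divide efficiencies by their geometric mean over ``index_set``.

    The output has geometric mean exactly 1 over the index set; the map is
    a projection (idempotent).  ``index_set`` holds 0-based taxon indices.
    """
    e_raw = np.asarray(e_raw, dtype=float)
    idx = np.asarray(list(index_set), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("index_set must be nonempty")
    log_gm = np.log(e_raw[..., idx]).mean(axis=-1, keepdims=True)
    return e_raw / np.exp(log_gm)


def covariate_mean(beta0, beta1, X_i):
    """Per-taxon prior mean of log concentration, ``beta0 + beta1 * X_i``."""
    return np.asarray(beta0, dtype=float) + np.asarray(beta1, dtype=float) * X_i


def _poisson_logpmf(v, mu):
    return v * np.log(mu) - mu - gammaln(v + 1.0)


def _normal_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def _lognormal_logpdf(x, log_var):
    lx = np.log(x)
    return -lx - 0.5 * (_LOG_2PI + np.log(log_var) + lx**2 / log_var)


def _invgamma_logpdf(x, shape, scale):
    return (
        shape * np.log(scale) - gammaln(shape) - (shape + 1.0) * np.log(x) - scale / x
    )


def log_joint_density(state: LatentState, data, spec: ModelSpec, components: bool = False):
    """Log joint density of data and latent state under ``spec``.

    Includes all normalizing constants (Poisson and multinomial log-pmfs
    are exact).  With ``components=True`` returns a dict of the additive
    pieces: ``poisson_V``, ``multinomial_W``, ``mu_prior``, ``beta_prior``,
    ``Sigma_prior`` and ``efficiency_prior`` (the latter zero under the
    efficiency-naive variant, whose e is fixed at 1).
    """
    hyper = spec.hyper
    W = np.asarray(data.W, dtype=float)
    V = np.asarray(data.V, dtype=float)
    M = np.asarray(data.M, dtype=float)
    qobs = data.qobs
    n, q = W.shape
    mu, e = state.mu, state.e
    if mu.shape != (n, q) or e.shape != (q,):
        raise ValueError("state dimensions do not match the data")
    if spec.variant == "efficiency_naive" and not np.allclose(e, 1.0):
        raise ValueError("efficiency_naive requires e = 1 for every taxon")

    poisson_v = float(_poisson_logpmf(V, mu[:, :qobs]).sum())

    p = relative_abundance_probs(mu, e)
    multinomial_w = float(
        (gammaln(M + 1.0) - gammaln(W + 1.0).sum(axis=1) + (W * np.log(p)).sum(axis=1)).sum()
    )

    log_mu = np.log(mu)
    if spec.covariate_adjusted:
        beta = np.asarray(state.beta, dtype=float)
        if beta.shape != (2, q):
            raise ValueError("covariate model requires beta of shape (2, q)")
        X = np.asarray(data.covariates.X, dtype=float)
        mean = beta[0][None, :] + X[:, None] * beta[1][None, :]
        beta_prior = float(
            _normal_logpdf(beta[0], 0.0, hyper.sigma_beta0_sq).sum()
            + _normal_logpdf(beta[1], 0.0, hyper.sigma_beta1_sq).sum()
        )
    else:
        beta = np.asarray(state.beta, dtype=float)
        if beta.shape != (q,):
            raise ValueError("beta must have length q")
        mean = beta[None, :]
        beta_prior = float(_normal_logpdf(beta, 0.0, hyper.sigma_beta_sq).sum())

    mu_prior = float(_normal_logpdf(log_mu, mean, state.Sigma_diag[None, :]).sum())
    sigma_prior = float(_lognormal_logpdf(state.Sigma_diag, hyper.sigma_Sigma_sq).sum())

    if spec.variant == "varying_efficiency":
        efficiency_prior = float(
            _lognormal_logpdf(e, state.sigma_e_sq).sum()
            + _invgamma_logpdf(state.sigma_e_sq, hyper.alpha_sigma, hyper.kappa_sigma)
        )
    else:
        efficiency_prior = 0.0

    parts = {
        "poisson_V": poisson_v,
        "multinomial_W": multinomial_w,
        "mu_prior": mu_prior,
        "beta_prior": beta_prior,
        "Sigma_prior": sigma_prior,
        "efficiency_prior": efficiency_prior,
    }
    if components:
        return parts
    return float(sum(parts.values()))


class UnconstrainedPosterior:
    """Log posterior and gradient on an unconstrained parameterization.

    Three devices keep the geometry well conditioned; all are exact
    (linear or smooth bijections with the proper Jacobians), so the
    posterior itself is unchanged:

    * log-transforms for the positive parameters (Sigma_jj, sigma_e^2);
    * read-scale coordinates: the sampler works with
      a_ij = log mu_ij + log e_j and beta'_j = beta_j + log e_j, so the
      tight multinomial constraint (precision ~ W_ij) involves a_ij alone
      and the shared efficiency log e_j appears only in the much looser
      Poisson and prior terms -- removing an n-way ridge between each
      efficiency and its column of concentrations.  For taxa without
      concentration data this leaves log e_j driven by its prior, as it
      should be: such an efficiency is not identified;
    * a per-cell mix of centered and non-centered coordinates for a_ij:
      a cell is sampled on its natural scale where the likelihood pins it
      down (counts >= 10) and as a standardized residual of its prior
      otherwise.

    Packed layout of theta:

        eta    (n*q)  mixed centered/non-centered read-scale coords
        beta   (q, or 2q stacked beta0,beta1 in the covariate model)
               (shifted: beta' = beta + log e; beta1 is never shifted)
        z_sig  (q)    log Sigma_jj
        zeta   (q)    log-efficiency coords (varying-efficiency only):
                      natural log e_j for observed taxa, log e_j / sigma_e
                      for unobserved taxa
        z_se   (1)    log sigma_e^2 (varying-efficiency only)
    """

    #: likelihood information (counts) above which a latent is centered
    CENTER_CUTOFF = 10.0

    def __init__(self, data, spec: ModelSpec):
        self.spec = spec
        self.W = np.asarray(data.W, dtype=float)
        self.V = np.asarray(data.V, dtype=float)
        self.M = np.asarray(data.M, dtype=float)
        self.qobs = data.qobs
        self.n, self.q = self.W.shape
        self.varying = spec.variant == "varying_efficiency"
        self.covariate = spec.covariate_adjusted
        if self.covariate:
            if data.covariates is None:
                raise ValueError("covariate-adjusted model needs covariates")
            self.X = np.asarray(data.covariates.X, dtype=float)
        n, q, qobs = self.n, self.q, self.qobs
        info = self.W.astype(float).copy()
        info[:, :qobs] += self.V
        self.center_mu = info >= self.CENTER_CUTOFF  # (n, q) bool
        self.obs_taxon = np.arange(q) < qobs  # (q,) bool
        # Which columns carry their efficiency inside the sampled
        # coordinate (a = log mu + log e): always the unobserved taxa
        # (identification), and observed taxa whose read total exceeds
        # their concentration total, so the shared log e_j sits in the
        # looser of the two likelihood terms.
        shift = ~self.obs_taxon
        shift[:qobs] = self.W[:, :qobs].sum(axis=0) > self.V.sum(axis=0)
        self.shift_e = shift  # (q,) bool
        self.n_beta = 2 * q if self.covariate else q
        self.dim = n * q + self.n_beta + q + (q + 1 if self.varying else 0)
        # numba fast path (reference NumPy path kept for the covariate
        # model and as the correctness oracle)
        from . import _kernels

        self._kernel = (
            _kernels.logp_grad_kernel
            if (_kernels.HAVE_NUMBA and not self.covariate)
            else None
        )
        if self._kernel is not None:
            self._kW = np.ascontiguousarray(self.W)
            self._kV = np.ascontiguousarray(self.V)
            self._kM = np.ascontiguousarray(self.M)
        self._slices = {}
        at = 0
        for name, size in (
            ("eta", n * q),
            ("beta", self.n_beta),
            ("z_sig", q),
            ("zeta", q if self.varying else 0),
            ("z_se", 1 if self.varying else 0),
        ):
            self._slices[name] = slice(at, at + size)
            at += size

    def _mean(self, beta):
        if self.covariate:
            b0, b1 = beta[: self.q], beta[self.q :]
            return b0[None, :] + self.X[:, None] * b1[None, :]
        return np.broadcast_to(beta[None, :], (self.n, self.q))

    def initial_inv_mass(self) -> np.ndarray:
        """Heuristic diagonal inverse mass from likelihood curvature.

        Approximates the per-coordinate Fisher information from the counts
        (multinomial information ~ W, Poisson information ~ V, plus the
        prior) and returns its reciprocal.  Used to precondition the
        sampler before warmup refines the mass matrix empirically.
        """
        n, q, qobs = self.n, self.q, self.qobs
        info_a = self.W + 1.0
        info_a[:, :qobs] += self.V
        info_eta = np.where(self.center_mu, info_a, 1.0 + self.W)
        info_beta = np.full(self.n_beta, float(n) + 1.0)
        info_sig = np.full(q, 0.5 * n + 1.0)
        parts = [info_eta.ravel(), info_beta, info_sig]
        if self.varying:
            col = np.zeros(q)
            col[:qobs] = np.minimum(self.V.sum(axis=0), self.W[:, :qobs].sum(axis=0))
            info_zeta = np.where(self.obs_taxon, col + 4.0, 1.0)
            parts += [info_zeta, [0.5 * q + 1.0]]
        return 1.0 / np.concatenate([np.asarray(p, float) for p in parts])

    def _z_e(self, theta):
        if not self.varying:
            return np.zeros(self.q), np.zeros(self.q), 0.0
        zeta = theta[self._slices["zeta"]]
        z_se = float(theta[self._slices["z_se"]][0])
        z_e = np.where(self.obs_taxon, zeta, np.exp(0.5 * z_se) * zeta)
        return z_e, zeta, z_se

    def unpack(self, theta):
        """Natural-scale pieces (z_mu = log mu, z_e = log e, ...) of theta."""
        n, q = self.n, self.q
        eta = theta[self._slices["eta"]].reshape(n, q)
        beta_s = theta[self._slices["beta"]]
        z_sig = theta[self._slices["z_sig"]]
        z_e, zeta, z_se = self._z_e(theta)
        c = self.center_mu
        a = np.where(c, eta, self._mean(beta_s) + np.exp(0.5 * z_sig)[None, :] * eta)
        shift = z_e * self.shift_e
        z_mu = a - shift[None, :]
        beta = beta_s.copy()
        beta[: q] -= shift  # beta, or beta0 in the covariate model
        return {
            "z_mu": z_mu, "beta": beta, "z_sig": z_sig,
            "z_e": z_e, "z_se": z_se, "eta": eta, "zeta": zeta,
        }

    def pack(self, z_mu, beta, z_sig, z_e=None, z_se=None):
        """Pack natural-scale values into the sampling parameterization."""
        q = self.q
        beta = np.ravel(np.asarray(beta, dtype=float)).copy()
        z_sig = np.ravel(np.asarray(z_sig, dtype=float))
        a = np.asarray(z_mu, dtype=float)
        if self.varying:
            z_se = float(z_se)
            z_e = np.asarray(z_e, dtype=float)
            shift = z_e * self.shift_e
            a = a + shift[None, :]
            beta[: q] += shift
        eta_nc = (a - self._mean(beta)) / np.exp(0.5 * z_sig)[None, :]
        eta = np.where(self.center_mu, a, eta_nc)
        parts = [eta.ravel(), beta, z_sig]
        if self.varying:
            zeta = np.where(self.obs_taxon, z_e, z_e / np.exp(0.5 * z_se))
            parts += [np.ravel(zeta), [z_se]]
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def state(self, theta) -> LatentState:
        p = self.unpack(theta)
        beta = p["beta"].reshape(2, self.q) if self.covariate else p["beta"]
        return LatentState(
            mu=np.exp(p["z_mu"]),
            e=np.exp(p["z_e"]),
            beta=beta,
            Sigma_diag=np.exp(p["z_sig"]),
            sigma_e_sq=float(np.exp(p["z_se"])),
        )

    def constrain(self, thetas):
        """Vectorized draw extraction: (S, dim) -> dict of natural arrays."""
        thetas = np.atleast_2d(thetas)
        S = thetas.shape[0]
        n, q = self.n, self.q
        eta = thetas[:, self._slices["eta"]].reshape(S, n, q)
        beta_s = thetas[:, self._slices["beta"]].copy()
        z_sig = thetas[:, self._slices["z_sig"]]
        if self.covariate:
            mean = beta_s[:, None, :q] + self.X[None, :, None] * beta_s[:, None, q:]
        else:
            mean = beta_s[:, None, :]
        a = np.where(
            self.center_mu[None, :, :],
            eta,
            mean + np.exp(0.5 * z_sig)[:, None, :] * eta,
        )
        if self.varying:
            z_se = thetas[:, self._slices["z_se"]][:, 0]
            zeta = thetas[:, self._slices["zeta"]]
            z_e = np.where(
                self.obs_taxon[None, :], zeta, np.exp(0.5 * z_se)[:, None] * zeta
            )
            shift = z_e * self.shift_e[None, :]
            z_mu = a - shift[:, None, :]
            beta_s[:, :q] -= shift
            sigma_e_sq = np.exp(z_se)
        else:
            z_e = np.zeros((S, q))
            z_mu = a
            sigma_e_sq = np.ones(S)
        return {
            "mu": np.exp(z_mu),
            "e": np.exp(z_e),
            "beta": beta_s.reshape(S, 2, q) if self.covariate else beta_s,
            "Sigma_diag": np.exp(z_sig),
            "sigma_e_sq": sigma_e_sq,
        }

    def logp_grad(self, theta):
        """Return (log posterior, gradient); -inf and zeros if not finite."""
        if self._kernel is not None:
            hyper = self.spec.hyper
            grad = np.empty_like(theta)
            # pad zeta/z_se offsets for the efficiency-naive variant; the
            # kernel never touches them when varying is False
            th = theta
            if not self.varying:
                th = np.concatenate([theta, np.zeros(self.q + 1)])
                grad = np.empty_like(th)
            logp = self._kernel(
                th,
                self._kW,
                self._kV,
                self._kM,
                self.center_mu,
                self.shift_e,
                self.obs_taxon,
                self.qobs,
                self.varying,
                hyper.sigma_beta_sq,
                hyper.sigma_Sigma_sq,
                hyper.alpha_sigma,
                hyper.kappa_sigma,
                grad,
            )
            if not self.varying:
                grad = grad[: self.dim]
            if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
                return -np.inf, np.zeros(self.dim)
            return float(logp), grad
        return self._logp_grad_numpy(theta)

    def _logp_grad_numpy(self, theta):
        """Reference implementation (always used for the covariate model)."""
        hyper = self.spec.hyper
        n, q, qobs = self.n, self.q, self.qobs
        eta = theta[self._slices["eta"]].reshape(n, q)
        beta_s = theta[self._slices["beta"]]
        z_sig = theta[self._slices["z_sig"]]
        c = self.center_mu
        nc = ~c
        obs = self.obs_taxon

        grad = np.zeros_like(theta)

        with np.errstate(over="ignore", invalid="ignore"):
            s_sig = np.exp(0.5 * z_sig)
            inv_sig = np.exp(-z_sig)
            mean = self._mean(beta_s)
            a = np.where(c, eta, mean + s_sig[None, :] * eta)
            if self.varying:
                zeta = theta[self._slices["zeta"]]
                z_se = float(theta[self._slices["z_se"]][0])
                t_e = np.exp(0.5 * z_se)
                se = np.exp(z_se)
                z_e = np.where(obs, zeta, t_e * zeta)
            else:
                z_e = np.zeros(q)

            sh = self.shift_e.astype(float)
            # Poisson on natural log mu = a - shift * z_e for observed taxa
            z_mu_obs = a[:, :qobs] - (sh * z_e)[None, :qobs]
            mu_obs = np.exp(z_mu_obs)
            logp = float((self.V * z_mu_obs - mu_obs).sum())
            pois_resid = self.V - mu_obs  # (n, qobs)
            g_a = np.zeros((n, q))
            g_a[:, :qobs] = pois_resid

            # multinomial argument: log mu + log e = a + (1 - shift) * z_e
            m_arg = a + ((1.0 - sh) * z_e)[None, :]
            amax = m_arg.max(axis=1, keepdims=True)
            expa = np.exp(m_arg - amax)
            sa = expa.sum(axis=1, keepdims=True)
            logp += float(
                (self.W * m_arg).sum()
                - (self.M * (np.log(sa[:, 0]) + amax[:, 0])).sum()
            )
            mult_resid = self.W - self.M[:, None] * (expa / sa)
            g_a += mult_resid

            # prior on log mu in sampled coords: N(a; mean, Sigma)
            r = eta - mean  # centered-coordinate residual
            logp += float(
                -0.5 * ((r**2 * inv_sig[None, :] + z_sig[None, :]) * c).sum()
                - 0.5 * (eta**2 * nc).sum()
            )
            g_eta = np.where(
                c,
                g_a - r * inv_sig[None, :],
                g_a * s_sig[None, :] - eta,
            )
            grad[self._slices["eta"]] = g_eta.ravel()

            # beta prior (on the natural beta = beta' - log e) and chain
            # rule through the prior mean
            g_mean = np.where(c, r * inv_sig[None, :], g_a)
            if self.covariate:
                b0, b1 = beta_s[:q] - sh * z_e, beta_s[q:]
                logp += float(
                    -0.5 * (b0**2).sum() / hyper.sigma_beta0_sq
                    - 0.5 * (b1**2).sum() / hyper.sigma_beta1_sq
                )
                g_beta = np.concatenate(
                    [
                        g_mean.sum(axis=0) - b0 / hyper.sigma_beta0_sq,
                        (self.X[:, None] * g_mean).sum(axis=0)
                        - b1 / hyper.sigma_beta1_sq,
                    ]
                )
                g_ze_beta = sh * b0 / hyper.sigma_beta0_sq
            else:
                b_nat = beta_s - sh * z_e
                logp += float(-0.5 * (b_nat**2).sum() / hyper.sigma_beta_sq)
                g_beta = g_mean.sum(axis=0) - b_nat / hyper.sigma_beta_sq
                g_ze_beta = sh * b_nat / hyper.sigma_beta_sq
            grad[self._slices["beta"]] = g_beta

            # lognormal prior on Sigma_jj + Jacobian: z_sig ~ N(0, sigma_Sigma^2)
            g_sig = (
                0.5 * ((r**2 * inv_sig[None, :] - 1.0) * c).sum(axis=0)
                + 0.5 * (g_a * eta * s_sig[None, :] * nc).sum(axis=0)
            )
            logp += float(-0.5 * (z_sig**2).sum() / hyper.sigma_Sigma_sq)
            grad[self._slices["z_sig"]] = g_sig - z_sig / hyper.sigma_Sigma_sq

            if self.varying:
                # d logp / d z_e: Poisson where shifted, multinomial where
                # not, plus the beta prior for shifted columns
                g_ze = g_ze_beta + (1.0 - sh) * mult_resid.sum(axis=0)
                g_ze[:qobs] -= sh[:qobs] * pois_resid.sum(axis=0)
                # centered: z_e ~ N(0, sigma_e^2); non-centered: zeta std
                # normal
                logp += float(
                    -0.5 * (((zeta**2) / se + z_se) * obs).sum()
                    - 0.5 * (zeta**2 * ~obs).sum()
                )
                grad[self._slices["zeta"]] = np.where(
                    obs, g_ze - zeta / se, g_ze * t_e - zeta
                )
                # InvGamma(a, k) on sigma_e^2 + Jacobian
                logp += float(
                    -hyper.alpha_sigma * z_se - hyper.kappa_sigma * np.exp(-z_se)
                )
                grad[self._slices["z_se"]] = (
                    0.5 * (((zeta**2) / se - 1.0) * obs).sum()
                    + 0.5 * t_e * float((g_ze * zeta * (~obs)).sum())
                    - hyper.alpha_sigma
                    + hyper.kappa_sigma * np.exp(-z_se)
                )

        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(theta)
        return logp, grad
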