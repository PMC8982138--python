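"""Estimator interface to the Bayesian joint abundance model.

``BayesianAbundanceEstimator`` follows the fit/predict convention: ``fit``
takes the read counts ``X = W`` (n samples x q taxa, observed taxa first)
and concentrations ``y = V`` (n x qobs), samples the posterior, and
exposes posterior summaries as fitted attributes.  The scaling-factor
baseline lives in :class:`jointabund.naive.NaiveScalingEstimator` with the
same interface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import inference
from .data import ConcentrationTable, CountTable, CovariateDesign, PairedDataset
from .intervals import IntervalSet, credible_interval, predict_unobserved
from .model import Hyperparameters, ModelSpec

__all__ = ["BayesianAbundanceEstimator"]


def _as_paired(X, y, covariates=None) -> PairedDataset:
    if isinstance(X, PairedDataset):
        return X
    W = np.asarray(X)
    V = np.asarray(y)
    if W.ndim != 2 or V.ndim != 2 or W.shape[0] != V.shape[0]:
        raise ValueError("W and V must be 2-d with matching sample counts")
    n, q = W.shape
    sample_ids = [f"sample_{i + 1:03d}" for i in range(n)]
    taxon_ids = [f"taxon_{j + 1:03d}" for j in range(q)]
    counts = CountTable(W, sample_ids, taxon_ids)
    conc = ConcentrationTable(V, sample_ids, taxon_ids[: V.shape[1]])
    cov = None
    if covariates is not None:
        cov = (
            covariates
            if isinstance(covariates, CovariateDesign)
            else CovariateDesign(np.asarray(covariates, dtype=float))
        )
    return PairedDataset(counts, conc, cov)


class BayesianAbundanceEstimator(BaseEstimator):
    """Hierarchical Bayesian estimator of absolute microbial abundance.

    Jointly models sequencing counts (multinomial) and observed
    concentrations (Poisson) with taxon-specific detection efficiencies
    under a lognormal prior hierarchy, sampled by NUTS.

    Parameters
    ----------
    variant : {"varying_efficiency", "efficiency_naive"}
        Whether detection efficiencies are modeled (recommended) or fixed
        at 1.
    covariate_adjusted : bool
        Model the prior mean of log concentration as beta0 + beta1 * x_i.
    centering : {"soft", "hard_observed", "hard_all"}
        Identifiability device for the efficiencies.
    sigma_beta_sq, sigma_Sigma_sq, alpha_sigma, kappa_sigma,
    sigma_beta0_sq, sigma_beta1_sq : float
        Prior hyperparameters; see :class:`jointabund.model.Hyperparameters`.
    alpha : float
        Interval miscoverage level (intervals at level 1 - alpha).
    chains, warmup, iters, seed, init_strategy, target_accept,
    max_treedepth :
        Sampler settings; see :class:`jointabund.inference.McmcConfig`.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Pooled post-warmup posterior draws.
    diagnostics_ : DiagnosticsReport
        Classic split Gelman-Rubin R-hat (plus rank-normalized R-hat and
        ESS) for every sampled scalar.
    mu_mean_ : (n, q) posterior mean concentrations.
    efficiency_mean_ : (q,) posterior mean detection efficiencies.
    qobs_ : number of observed taxa.
    """

    def __init__(
        self,
        variant: str = "varying_efficiency",
        covariate_adjusted: bool = False,
        centering: str = "soft",
        sigma_beta_sq: float = 50.0,
        sigma_Sigma_sq: float = 50.0,
        alpha_sigma: float = 2.0,
        kappa_sigma: float = 1.0,
        sigma_beta0_sq: float = 1.62**2,
        sigma_beta1_sq: float = 1.0,
        alpha: float = 0.05,
        chains: int = 4,
        warmup: int = 1000,
        iters: int = 1500,
        seed: int = 0,
        init_strategy: str = "random",
        target_accept: float = 0.8,
        max_treedepth: int = 10,
    ):
        self.variant = variant
        self.covariate_adjusted = covariate_adjusted
        self.centering = centering
        self.sigma_beta_sq = sigma_beta_sq
        self.sigma_Sigma_sq = sigma_Sigma_sq
        self.alpha_sigma = alpha_sigma
        self.kappa_sigma = kappa_sigma
        self.sigma_beta0_sq = sigma_beta0_sq
        self.sigma_beta1_sq = sigma_beta1_sq
        self.alpha = alpha
        self.chains = chains
        self.warmup = warmup
        self.iters = iters
        self.seed = seed
        self.init_strategy = init_strategy
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            variant=self.variant,
            covariate_adjusted=self.covariate_adjusted,
            centering=self.centering,
            hyper=Hyperparameters(
                sigma_beta_sq=self.sigma_beta_sq,
                sigma_Sigma_sq=self.sigma_Sigma_sq,
                alpha_sigma=self.alpha_sigma,
                kappa_sigma=self.kappa_sigma,
                sigma_beta0_sq=self.sigma_beta0_sq,
                sigma_beta1_sq=self.sigma_beta1_sq,
                alpha_level=self.alpha,
            ),
        )

    def _mcmc(self) -> inference.McmcConfig:
        return inference.McmcConfig(
            chains=self.chains,
            warmup_iters=self.warmup,
            total_iters=self.iters,
            seed=self.seed,
            init_strategy=self.init_strategy,
            target_accept=self.target_accept,
            max_treedepth=self.max_treedepth,
        )

    def fit(self, X, y=None, covariates=None):
        """Sample the posterior given counts ``X = W`` and concentrations
        ``y = V``.  ``X`` may also be a ready-made :class:`PairedDataset`
        (then ``y`` is ignored)."""
        data = _as_paired(X, y, covariates)
        self.data_ = data
        self.draws_, self.diagnostics_ = inference.fit(data, self._spec(), self._mcmc())
        self.mu_mean_ = self.draws_.mu.mean(axis=0)
        self.efficiency_mean_ = self.draws_.e.mean(axis=0)
        self.n_features_in_ = data.q
        self.qobs_ = data.qobs
        return self

    def predict(self, X=None):
        """Posterior mean concentrations (n, q) for the fitted samples."""
        self._check_fitted()
        return self.mu_mean_

    def credible_intervals(self, alpha: float | None = None) -> IntervalSet:
        """Equal-tailed posterior credible intervals for every mu_ij,
        including sample-taxon pairs with a zero read count."""
        self._check_fitted()
        a = self.alpha if alpha is None else alpha
        lo, hi = credible_interval(self.draws_.mu, a)
        return IntervalSet(lo, hi, 1 - a, "mu_credible", "quantile")

    def prediction_intervals(
        self, alpha: float | None = None, method: str = "wald", seed=0
    ):
        """Point predictions and intervals for the unobserved concentrations
        V_ij, j > qobs; returns ``(V_hat, IntervalSet)``."""
        self._check_fitted()
        a = self.alpha if alpha is None else alpha
        return predict_unobserved(
            self.draws_.mu, self.qobs_, alpha=a, method=method, seed=seed
        )

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
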