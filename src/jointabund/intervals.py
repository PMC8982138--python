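"""Interval construction from posterior draws.

Credible intervals for the true concentrations mu are empirical posterior
quantiles (linear interpolation of order statistics).  Prediction
intervals for unrealized concentrations V come in two flavors: a Wald
interval using the iterated-variance identity Var(V) = E[mu] + Var(mu)
with the lower limit truncated at zero, and a posterior-predictive
quantile interval built from one Poisson draw per posterior mu draw.
Credible intervals exist for every sample and taxon, including pairs with
a zero read count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IntervalSet",
    "credible_interval",
    "wald_prediction_interval",
    "quantile_prediction_interval",
    "predict_unobserved",
]

_MIN_DRAWS = 100


@dataclass(frozen=True)
class IntervalSet:
    """Elementwise lower/upper bounds at level ``1 - alpha``."""

    lower: np.ndarray
    upper: np.ndarray
    level: float
    target: str  # "mu_credible" or "V_prediction"
    method: str  # "quantile" or "wald"

    def __post_init__(self):
        if not (np.asarray(self.lower) <= np.asarray(self.upper) + 1e-12).all():
            raise ValueError("lower bounds exceed upper bounds")

    def contains(self, truth) -> np.ndarray:
        """Closed-interval membership of ``truth``, elementwise."""
        t = np.asarray(truth)
        return (self.lower <= t) & (t <= self.upper)


def _check_draws(draws):
    draws = np.asarray(draws, dtype=float)
    if draws.shape[0] < _MIN_DRAWS:
        raise ValueError(
            f"need at least {_MIN_DRAWS} posterior draws, got {draws.shape[0]}"
        )
    return draws


def credible_interval(mu_draws, alpha: float = 0.05):
    """Equal-tailed (alpha/2, 1-alpha/2) posterior quantile interval.

    ``mu_draws`` has draws along the first axis; trailing axes are handled
    elementwise.  Quantiles use linear interpolation of order statistics.
    """
    draws = _check_draws(mu_draws)
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    return lo, hi


def wald_prediction_interval(mu_draws, alpha: float = 0.05):
    """``max(0, mean +/- z * sqrt(mean + var))`` over the posterior draws."""
    draws = _check_draws(mu_draws)
    m = draws.mean(axis=0)
    v = draws.var(axis=0, ddof=0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(m + v)
    return np.maximum(0.0, m - half), m + half


def quantile_prediction_interval(mu_draws, alpha: float = 0.05, seed=0):
    """Posterior-predictive quantile interval.

    One Poisson variate is drawn per posterior mu draw; the interval is
    the empirical (alpha/2, 1-alpha/2) quantile pair of those variates.
    """
    draws = _check_draws(mu_draws)
    rng = np.random.default_rng(seed)
    v = rng.poisson(draws)
    lo, hi = np.quantile(v, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    return lo, hi


def predict_unobserved(mu_draws, qobs: int, alpha: float = 0.05,
                       method: str = "wald", point: str = "mean", seed=0):
    """Point predictions and prediction intervals for taxa without
    concentration data (columns ``qobs..q-1`` of the aligned table).

    ``mu_draws`` is the (S, n, q) array of posterior concentration draws
    (e.g. ``PosteriorDraws.mu``).  Returns ``(V_hat, IntervalSet)``; both
    empty (zero columns) when every taxon is observed.  ``point`` selects
    posterior mean (default) or median.
    """
    mu_draws = np.asarray(mu_draws, dtype=float)
    S, n, q = mu_draws.shape
    block = mu_draws[:, :, qobs:]
    if block.shape[2] == 0:
        empty = np.zeros((n, 0))
        return empty, IntervalSet(empty, empty, 1 - alpha, "V_prediction", method)
    v_hat = block.mean(axis=0) if point == "mean" else np.median(block, axis=0)
    if method == "wald":
        lo, hi = wald_prediction_interval(block, alpha)
    elif method == "quantile":
        lo, hi = quantile_prediction_interval(block, alpha, seed=seed)
    else:
        raise ValueError("method must be 'wald' or 'quantile'")
    return v_hat, IntervalSet(lo, hi, 1 - alpha, "V_prediction", method)
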