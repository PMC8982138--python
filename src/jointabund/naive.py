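"""Scaling-factor ("naive") estimator of absolute abundance.

The estimator rescales each sample's read counts by the ratio of total
observed concentration to total observed reads over the taxa with
concentration data:

    s_i   = sum_{j<=qobs} V_ij / sum_{j<=qobs} W_ij
    mu_ij = s_i * W_ij

It assumes every taxon is detected with equal efficiency.  Delta-method
confidence intervals for mu_ij and prediction intervals for unrealized
V_ij are available on the log scale wherever ``W_ij > 0``; pairs with a
zero count have no interval (flagged as missing, never fabricated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "scaling_factor",
    "naive_point",
    "naive_log_variance",
    "naive_confidence_interval",
    "naive_prediction_interval",
    "NaiveScalingEstimator",
]


class UndefinedScalingError(ValueError):
    """Raised when a sample has no observed reads among the observed taxa."""


def scaling_factor(V_row, W_obs_row, sample_id=None) -> float:
    """Per-sample scaling factor ``sum(V_row) / sum(W_obs_row)``.

    Both arguments range over the observed subcomposition (the qobs taxa
    with concentration data) of a single sample.
    """
    V_row = np.asarray(V_row, dtype=float)
    W_obs_row = np.asarray(W_obs_row, dtype=float)
    total_w = W_obs_row.sum()
    if total_w <= 0:
        label = f" (sample {sample_id})" if sample_id is not None else ""
        raise UndefinedScalingError(
            f"scaling factor undefined{label}: no observed reads among the "
            "taxa with concentration data"
        )
    return float(V_row.sum() / total_w)


def naive_point(s_i: float, W_row) -> np.ndarray:
    """Point estimate ``s_i * W_row``; zeros in W are preserved exactly."""
    if s_i <= 0:
        raise ValueError("scaling factor must be positive")
    return s_i * np.asarray(W_row, dtype=float)


def naive_log_variance(V_row, W_row, qobs: int, j: int) -> float:
    """Delta-method variance of ``log(s_i * W_ij)`` for one sample and taxon.

    Writing T_V = sum of observed concentrations and T_W = sum of observed
    reads for the sample, the plug-in variance is

        1/T_V + 1/W_ij - 1/T_W   for observed taxa (j < qobs), and
        1/T_V + 1/W_ij + 1/T_W   for unobserved taxa (j >= qobs),

    the sign of the 1/T_W term following from the multinomial covariance
    between W_ij and T_W (W_ij is a summand of T_W only when observed).
    Returns NaN when ``W_ij == 0`` (no interval exists); a negative
    computed variance is clamped to zero with a warning.
    """
    V_row = np.asarray(V_row, dtype=float)
    W_row = np.asarray(W_row, dtype=float)
    w_ij = W_row[j]
    if w_ij == 0:
        return float("nan")
    t_v = V_row.sum()
    t_w = W_row[:qobs].sum()
    if t_v <= 0 or t_w <= 0:
        raise ValueError("observed totals must be positive to estimate variance")
    sign = -1.0 if j < qobs else 1.0
    v = 1.0 / t_v + 1.0 / w_ij + sign / t_w
    if v < 0:
        warnings.warn(
            "negative delta-method variance estimate; clamping to 0", stacklevel=2
        )
        v = 0.0
    return float(v)


def _log_scale_interval(mu_hat: float, half_width_var: float, alpha: float):
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(half_width_var)
    log_mu = np.log(mu_hat)
    return float(np.exp(log_mu - half)), float(np.exp(log_mu + half))


def naive_confidence_interval(mu_hat: float, var_log: float, alpha: float = 0.05):
    """``exp(log mu_hat +/- z_{1-alpha/2} sqrt(var_log))``; None if mu_hat=0."""
    if mu_hat == 0 or np.isnan(var_log):
        return None
    return _log_scale_interval(mu_hat, var_log, alpha)


def naive_prediction_interval(mu_hat: float, var_log: float, alpha: float = 0.05):
    """As the confidence interval but with variance ``1/mu_hat + var_log``,
    accounting for Poisson realization noise in the future observation."""
    if mu_hat == 0 or np.isnan(var_log):
        return None
    return _log_scale_interval(mu_hat, 1.0 / mu_hat + var_log, alpha)


@dataclass(frozen=True)
class NaiveEstimate:
    s_hat: np.ndarray
    mu_hat: np.ndarray
    var_log_mu_hat: np.ndarray  # NaN where mu_hat == 0


class NaiveScalingEstimator(BaseEstimator):
    """Scaling-factor estimator with delta-method intervals.

    Parameters
    ----------
    alpha : float
        Interval miscoverage level; intervals have nominal level 1 - alpha.

    Attributes
    ----------
    s_hat_ : (n,) array of per-sample scaling factors.
    mu_hat_ : (n, q) array of point estimates (zero exactly where W is zero).
    var_log_mu_hat_ : (n, q) array of delta-method variances of log mu_hat,
        NaN where the estimate is zero.
    qobs_ : number of observed taxa (columns of V).
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        """Fit from counts ``X = W`` (n x q) and concentrations ``y = V``
        (n x qobs); observed taxa must occupy the leading columns of W."""
        W = np.asarray(X, dtype=float)
        V = np.asarray(y, dtype=float)
        if W.ndim != 2 or V.ndim != 2 or W.shape[0] != V.shape[0]:
            raise ValueError("W and V must be 2-d with matching sample counts")
        n, q = W.shape
        qobs = V.shape[1]
        if qobs > q:
            raise ValueError(f"qobs={qobs} exceeds q={q}")
        s = np.empty(n)
        for i in range(n):
            s[i] = scaling_factor(V[i], W[i, :qobs], sample_id=i)
        mu_hat = s[:, None] * W
        var_log = np.full((n, q), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n):
                for j in range(q):
                    if W[i, j] > 0:
                        var_log[i, j] = naive_log_variance(V[i], W[i], qobs, j)
        self.n_features_in_ = q
        self.qobs_ = qobs
        self.s_hat_ = s
        self.mu_hat_ = mu_hat
        self.var_log_mu_hat_ = var_log
        return self

    def predict(self, X=None):
        """Return the fitted point estimates ``mu_hat_``."""
        if not hasattr(self, "mu_hat_"):
            raise RuntimeError("estimator is not fitted")
        return self.mu_hat_

    def _intervals(self, extra_poisson: bool, alpha):
        alpha = self.alpha if alpha is None else alpha
        n, q = self.mu_hat_.shape
        lower = np.full((n, q), np.nan)
        upper = np.full((n, q), np.nan)
        for i in range(n):
            for j in range(q):
                mu = self.mu_hat_[i, j]
                v = self.var_log_mu_hat_[i, j]
                if mu == 0 or np.isnan(v):
                    continue
                fn = naive_prediction_interval if extra_poisson else naive_confidence_interval
                lower[i, j], upper[i, j] = fn(mu, v, alpha)
        return lower, upper

    def confidence_intervals(self, alpha: float | None = None):
        """(lower, upper) confidence bounds for mu; NaN where W_ij = 0."""
        return self._intervals(False, alpha)

    def prediction_intervals(self, alpha: float | None = None):
        """(lower, upper) prediction bounds for future V; NaN where W_ij = 0."""
        return self._intervals(True, alpha)
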