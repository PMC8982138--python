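"""Performance metrics, the replicated simulation study, and the
leave-one-taxon-out validation.

Metrics follow the simulation-study conventions: root mean squared error
(RMSE) of concentration estimates against the true mu over all retained
sample-taxon pairs; root mean squared prediction error (RMSPE) of
predicted against realized concentrations over the unobserved block
(j > qobs); and empirical coverage of nominal-level intervals, where
pairs whose scaling-factor estimate is zero are excluded for the naive
estimator only (its intervals do not exist there).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import PairedDataset
from .estimators import BayesianAbundanceEstimator
from .naive import NaiveScalingEstimator
from .simulate import SimulationConfig, simulate_paired

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "rmse",
    "rmspe",
    "empirical_coverage",
    "zero_fraction",
    "zero_fraction_study",
    "run_simulation_study",
    "jackknife_loo",
    "conditional_mean_relative_abundance",
]

_ESTIMATORS = ("naive", "efficiency_naive", "varying_efficiency")


@dataclass(frozen=True)
class MetricsReport:
    """Replicate-level performance summary for one estimator.

    ``rmse_mu_by_taxon`` and ``coverage_mu_by_taxon`` hold the same
    quantities broken down per taxon (columns of the aligned table);
    coverage entries are NaN for taxa whose every pair was excluded.
    """

    estimator: str
    rmse_mu: float
    rmspe_V: float
    coverage_mu: float
    coverage_V: float
    zero_fraction: float
    n_excluded_naive: int
    rmse_mu_by_taxon: np.ndarray | None = None
    coverage_mu_by_taxon: np.ndarray | None = None

    def __post_init__(self):
        for name in ("coverage_mu", "coverage_V", "zero_fraction"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _per_taxon(est, truth_mu, lower, upper, exclude=None):
    """Column-wise RMSE and interval coverage (NaN where all excluded)."""
    q = truth_mu.shape[1]
    rm = np.array([rmse(est[:, j], truth_mu[:, j]) for j in range(q)])
    cov = np.full(q, np.nan)
    for j in range(q):
        excl_j = None if exclude is None else exclude[:, j]
        if excl_j is not None and excl_j.all():
            continue
        cov[j] = empirical_coverage(
            lower[:, j], upper[:, j], truth_mu[:, j], exclude_mask=excl_j
        )
    return rm, cov


def rmse(est, truth, subset=None) -> float:
    """Root mean squared error over ``subset`` (a boolean mask; default all)."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("shape mismatch")
    d = est - truth
    if subset is not None:
        d = d[np.asarray(subset, dtype=bool)]
    if d.size == 0:
        raise ValueError("empty subset")
    return float(np.sqrt(np.mean(d**2)))


def rmspe(pred, realized, subset=None) -> float:
    """RMSE of predictions against realized values (the unobserved block)."""
    return rmse(pred, realized, subset)


def empirical_coverage(lower, upper, truth, exclude_mask=None) -> float:
    """Fraction of non-excluded pairs with ``lower <= truth <= upper``.

    Closed intervals: truth exactly on a bound counts as covered.
    ``exclude_mask`` marks pairs left out (used for the naive estimator,
    whose intervals do not exist at zero estimates).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    keep = np.ones(truth.shape, dtype=bool)
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)
    if not keep.any():
        raise ValueError("every pair excluded from coverage")
    inside = (lower[keep] <= truth[keep]) & (truth[keep] <= upper[keep])
    return float(inside.mean())


def zero_fraction(W) -> float:
    """Fraction of sample-taxon pairs with a zero read count."""
    W = np.asarray(W)
    return float((W == 0).mean())


def zero_fraction_study(
    q: int, n: int = 100, B: int = 50, seed: int = 0, qobs: int = 7, **cfg_kwargs
):
    """Average zero fraction over B equal-efficiency replicates.

    Replicates the taxon-number experiment without any model fitting:
    each replicate redraws the taxon-level means beta, simulates reads,
    applies the abundance floor, and records the fraction of retained
    sample-taxon pairs whose read count (hence scaling-factor estimate)
    is zero.  Returns ``(mean percent, total retained pairs)``.
    """
    seeds = np.random.SeedSequence([seed, q]).generate_state(B)
    fracs = []
    pairs = 0
    for b in range(B):
        cfg = SimulationConfig(
            q=q,
            qobs=min(qobs, q),
            n=n,
            sigma_e=0.0,
            seed=int(seeds[b] % (2**31)),
            **cfg_kwargs,
        )
        # the zero fraction needs no observed-taxon selection; build the
        # retained matrix directly
        from .simulate import abundance_filter, simulate_dataset

        try:
            truth, counts, _ = simulate_dataset(cfg)
            Wk = counts.W
        except RuntimeError:
            # fewer retained taxa than qobs: recompute without selection
            ss = np.random.SeedSequence(cfg.seed).spawn(6)
            r_pop, r_e, r_mu, r_m, r_v, r_w = (np.random.default_rng(s) for s in ss)
            beta = r_pop.normal(0.0, np.sqrt(cfg.beta_var), size=q)
            mu = np.exp(r_mu.normal(beta[None, :], 1.0, size=(n, q)))
            M = r_m.integers(cfg.M_low, cfg.M_high, endpoint=True, size=n)
            p = mu / mu.sum(axis=1, keepdims=True)
            W = np.vstack([r_w.multinomial(M[i], p[i]) for i in range(n)])
            Wk = W[:, abundance_filter(mu, cfg.abundance_floor)]
        fracs.append(zero_fraction(Wk))
        pairs += Wk.size
    return 100.0 * float(np.mean(fracs)), pairs


def _bayes_metrics(est, truth_mu, V_real, qobs, alpha):
    ci = est.credible_intervals(alpha)
    cov_mu = empirical_coverage(ci.lower, ci.upper, truth_mu)
    err_mu = rmse(est.mu_mean_, truth_mu)
    by_taxon = _per_taxon(est.mu_mean_, truth_mu, ci.lower, ci.upper)
    if qobs < truth_mu.shape[1]:
        v_hat, pis = est.prediction_intervals(alpha)
        realized = V_real[:, qobs:]
        cov_v = empirical_coverage(pis.lower, pis.upper, realized)
        err_v = rmspe(v_hat, realized)
    else:
        cov_v, err_v = float("nan"), float("nan")
    return err_mu, err_v, cov_mu, cov_v, by_taxon


def _naive_metrics(paired, truth_mu, V_real, alpha):
    est = NaiveScalingEstimator(alpha=alpha).fit(paired.W, paired.V)
    zero = est.mu_hat_ == 0
    lo, hi = est.confidence_intervals(alpha)
    cov_mu = empirical_coverage(lo, hi, truth_mu, exclude_mask=zero)
    err_mu = rmse(est.mu_hat_, truth_mu)
    qobs = paired.qobs
    if qobs < paired.q:
        lo_p, hi_p = est.prediction_intervals(alpha)
        realized = V_real[:, qobs:]
        cov_v = empirical_coverage(
            lo_p[:, qobs:], hi_p[:, qobs:], realized, exclude_mask=zero[:, qobs:]
        )
        err_v = rmspe(est.mu_hat_[:, qobs:], realized)
    else:
        cov_v, err_v = float("nan"), float("nan")
    rm_taxon, cov_taxon = _per_taxon(est.mu_hat_, truth_mu, lo, hi, exclude=zero)
    return MetricsReport(
        estimator="naive",
        rmse_mu=err_mu,
        rmspe_V=err_v,
        coverage_mu=cov_mu,
        coverage_V=cov_v,
        zero_fraction=zero_fraction(paired.W),
        n_excluded_naive=int(zero.sum()),
        rmse_mu_by_taxon=rm_taxon,
        coverage_mu_by_taxon=cov_taxon,
    )


def evaluate_replicate(
    paired: PairedDataset,
    truth_mu,
    V_real,
    estimators=_ESTIMATORS,
    alpha: float = 0.05,
    mcmc_kwargs=None,
):
    """Fit the requested estimators on one dataset and report metrics.

    ``truth_mu`` and ``V_real`` are the true concentrations and realized
    concentration draws aligned to the paired dataset's column order.
    """
    mcmc_kwargs = dict(mcmc_kwargs or {})
    out = []
    for name in estimators:
        if name == "naive":
            out.append(_naive_metrics(paired, truth_mu, V_real, alpha))
            continue
        est = BayesianAbundanceEstimator(variant=name, alpha=alpha, **mcmc_kwargs)
        est.fit(paired)
        err_mu, err_v, cov_mu, cov_v, by_taxon = _bayes_metrics(
            est, truth_mu, V_real, paired.qobs, alpha
        )
        out.append(
            MetricsReport(
                estimator=name,
                rmse_mu=err_mu,
                rmspe_V=err_v,
                coverage_mu=cov_mu,
                coverage_V=cov_v,
                zero_fraction=zero_fraction(paired.W),
                n_excluded_naive=0,
                rmse_mu_by_taxon=by_taxon[0],
                coverage_mu_by_taxon=by_taxon[1],
            )
        )
    return out


def run_simulation_study(
    configs,
    B: int = 10,
    estimators=_ESTIMATORS,
    alpha: float = 0.05,
    seed: int = 0,
    mcmc_kwargs=None,
    max_fits: int | None = None,
) -> pd.DataFrame:
    """Replicated study over a grid of simulation configurations.

    Returns one row per (configuration, replicate, estimator).  Replicates
    are fully seeded; a failed fit is recorded (``failed=True``) and the
    study continues.  ``max_fits`` warns when the projected number of
    Bayesian fits exceeds a budget guardrail.
    """
    configs = list(configs)
    n_bayes = sum(1 for e in estimators if e != "naive") * len(configs) * B
    if max_fits is not None and n_bayes > max_fits:
        warnings.warn(
            f"study projects {n_bayes} posterior fits (> budget {max_fits}); "
            "consider fewer replicates or configurations",
            stacklevel=2,
        )
    rows = []
    for ci, base in enumerate(configs):
        rep_seeds = np.random.SeedSequence([seed, ci]).generate_state(B)
        for b in range(B):
            cfg = SimulationConfig(
                **{
                    **base.__dict__,
                    "seed": int(rep_seeds[b] % (2**31)),
                }
            )
            fit_seed = int(rep_seeds[b] % (2**29))
            kw = {"seed": fit_seed, **dict(mcmc_kwargs or {})}
            try:
                truth, paired, mu_true, V_true = simulate_paired(cfg)
                reports = evaluate_replicate(
                    paired, mu_true, V_true, estimators, alpha, kw
                )
                for rep in reports:
                    rows.append(
                        {
                            "config": ci,
                            "replicate": b,
                            "sigma_e": cfg.sigma_e,
                            "q": cfg.q,
                            "q_retained": paired.q,
                            "qobs": cfg.qobs,
                            "failed": False,
                            **rep.__dict__,
                        }
                    )
            except Exception as err:  # noqa: BLE001 - flag and continue
                logger.warning("replicate %d of config %d failed: %s", b, ci, err)
                rows.append(
                    {
                        "config": ci,
                        "replicate": b,
                        "sigma_e": cfg.sigma_e,
                        "q": cfg.q,
                        "qobs": cfg.qobs,
                        "failed": True,
                        "estimator": "all",
                    }
                )
    return pd.DataFrame(rows)


def conditional_mean_relative_abundance(W_col, M) -> float:
    """Mean of ``W_ij / M_i`` over the samples where taxon j was detected.

    Undefined (NaN, with a warning) for an all-zero column.
    """
    W_col = np.asarray(W_col, dtype=float)
    M = np.asarray(M, dtype=float)
    present = W_col > 0
    if not present.any():
        warnings.warn("all-zero column: conditional mean undefined", stacklevel=2)
        return float("nan")
    return float((W_col[present] / M[present]).mean())


def jackknife_loo(
    paired: PairedDataset,
    estimators=_ESTIMATORS,
    alpha: float = 0.05,
    seed: int = 0,
    mcmc_kwargs=None,
) -> pd.DataFrame:
    """Leave-one-taxon-out validation on the observed subcomposition.

    ``paired`` must be restricted to the taxa with concentration data
    (qobs == q).  Each fold withholds one concentration column, refits,
    predicts the withheld concentrations, and scores prediction-interval
    coverage and mean squared prediction error against the withheld
    column.  Fold seeds derive from ``seed`` + the taxon index, so folds
    are order-independent.
    """
    from .data import ConcentrationTable, CountTable

    if paired.qobs < 2:
        raise ValueError("need at least two observed taxa to jackknife")
    if paired.qobs != paired.q:
        raise ValueError(
            "restrict the dataset to the observed taxa before jackknifing"
        )
    rows = []
    q = paired.q
    for k in range(q):
        held = paired.V[:, k].astype(float)
        order = [j for j in range(q) if j != k] + [k]
        W_fold = paired.W[:, order]
        taxa = [paired.counts.taxon_ids[j] for j in order]
        counts = CountTable(W_fold, paired.counts.sample_ids, taxa)
        conc = ConcentrationTable(
            paired.V[:, [j for j in range(q) if j != k]],
            paired.counts.sample_ids,
            [paired.counts.taxon_ids[j] for j in range(q) if j != k],
        )
        fold = PairedDataset(counts, conc, paired.covariates)
        for name in estimators:
            try:
                if name == "naive":
                    est = NaiveScalingEstimator(alpha=alpha).fit(fold.W, fold.V)
                    pred = est.mu_hat_[:, -1]
                    lo, hi = est.prediction_intervals(alpha)
                    lo, hi = lo[:, -1], hi[:, -1]
                    excl = est.mu_hat_[:, -1] == 0
                    cov = empirical_coverage(lo, hi, held, exclude_mask=excl)
                else:
                    kw = {"seed": seed + k, **dict(mcmc_kwargs or {})}
                    best = BayesianAbundanceEstimator(
                        variant=name, alpha=alpha, **kw
                    ).fit(fold)
                    v_hat, pis = best.prediction_intervals(alpha)
                    pred = v_hat[:, 0]
                    cov = empirical_coverage(pis.lower[:, 0], pis.upper[:, 0], held)
                mspe = float(np.mean((pred - held) ** 2))
                rows.append(
                    {
                        "left_out": paired.counts.taxon_ids[k],
                        "fold": k,
                        "estimator": name,
                        "coverage_V": cov,
                        "mspe": mspe,
                        "failed": False,
                    }
                )
            except Exception as err:  # noqa: BLE001 - flag and continue
                logger.warning("fold %d (%s) failed: %s", k, name, err)
                rows.append(
                    {
                        "left_out": paired.counts.taxon_ids[k],
                        "fold": k,
                        "estimator": name,
                        "coverage_V": float("nan"),
                        "mspe": float("nan"),
                        "failed": True,
                    }
                )
    return pd.DataFrame(rows)
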