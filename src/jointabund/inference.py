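"""Posterior sampling, initialization, and convergence diagnostics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import PairedDataset
from .model import ModelSpec, UnconstrainedPosterior, hard_center
from .naive import UndefinedScalingError, scaling_factor
from .nuts import sample_chain

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "DiagnosticsReport",
    "initialize_chains",
    "fit",
    "gelman_rubin",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    Defaults are desk-scale (1000 warmup / 500 retained per chain, 4
    chains); the full-scale settings used for the published simulation
    study (10,000 warmup, 10,500 total) are available by configuration.
    """

    chains: int = 4
    warmup_iters: int = 1000
    total_iters: int = 1500
    seed: int = 0
    init_strategy: str = "random"
    target_accept: float = 0.8
    max_treedepth: int = 10

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.total_iters <= self.warmup_iters:
            raise ValueError("total_iters must exceed warmup_iters")
        if self.init_strategy not in ("naive_anchor", "random"):
            raise ValueError("init_strategy must be 'naive_anchor' or 'random'")

    @property
    def retained_iters(self) -> int:
        return self.total_iters - self.warmup_iters


@dataclass
class PosteriorDraws:
    """Pooled post-warmup draws with chain labels.

    ``beta`` has shape (S, q) or (S, 2, q) for the covariate-adjusted
    model.  ``e`` is all ones under the efficiency-naive variant.
    """

    mu: np.ndarray  # (S, n, q)
    e: np.ndarray  # (S, q)
    beta: np.ndarray
    Sigma_diag: np.ndarray  # (S, q)
    sigma_e_sq: np.ndarray  # (S,)
    chain: np.ndarray  # (S,) chain index of each draw
    spec: ModelSpec
    config: McmcConfig

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0]

    def by_chain(self, arr: np.ndarray) -> np.ndarray:
        """Reshape a pooled (S, ...) array to (chains, S_per_chain, ...)."""
        c = self.config.chains
        return arr.reshape(c, arr.shape[0] // c, *arr.shape[1:])


@dataclass
class DiagnosticsReport:
    rhat: dict  # parameter-group name -> array of classic split R-hat values
    rhat_rank_normalized: dict  # same, arviz rank-normalized variant
    ess: dict
    mu_rhat_median: float
    mu_rhat_iqr: tuple
    divergences: int
    max_treedepth_hits: int
    mean_accept: float

    def summary(self) -> str:
        lo, hi = self.mu_rhat_iqr
        return (
            f"median R-hat(mu)={self.mu_rhat_median:.3f} "
            f"IQR=[{lo:.3f}, {hi:.3f}], divergences={self.divergences}, "
            f"mean acceptance={self.mean_accept:.2f}"
        )


def gelman_rubin(chain_draws, split: bool = True) -> float:
    """Classic potential-scale-reduction factor for one scalar parameter.

    ``chain_draws`` is a (chains, draws) array.  Each chain is split in
    half by default.  Computes sqrt(((S-1)/S * W + B/S) / W) from the
    between- and within-chain variances; returns NaN (with a warning) when
    the within-chain variance is zero.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need at least 2 chains with at least 4 draws each")
    if split:
        half = x.shape[1] // 2
        x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, s = x.shape
    within = x.var(axis=1, ddof=1).mean()
    between = s * x.mean(axis=1).var(ddof=1)
    if within == 0:
        warnings.warn("zero within-chain variance; R-hat undefined", stacklevel=2)
        return float("nan")
    return float(np.sqrt(((s - 1) / s * within + between / s) / within))


def _naive_anchor_logmu(data: PairedDataset) -> np.ndarray:
    """log(s_i W_ij + 0.5): the scaling estimator with a half pseudo-count."""
    W, V = data.W, data.V
    n = data.n
    s = np.empty(n)
    global_s = None
    for i in range(n):
        try:
            s[i] = scaling_factor(V[i], W[i, : data.qobs], sample_id=data.counts.sample_ids[i])
        except UndefinedScalingError:
            if global_s is None:
                tot_w = W[:, : data.qobs].sum()
                global_s = V.sum() / tot_w if tot_w > 0 else 1.0
                logger.warning(
                    "sample %s has no reads among observed taxa; "
                    "falling back to the global scaling factor",
                    data.counts.sample_ids[i],
                )
            s[i] = global_s
    return np.log(s[:, None] * W + 0.5)


def initialize_chains(data: PairedDataset, spec: ModelSpec, mcmc: McmcConfig):
    """Initial unconstrained parameter vectors, one per chain.

    The anchor sets log mu at the naive estimate (with a 0.5 pseudo-count
    for zeros), beta at the column means of that matrix, Sigma_jj = 1,
    e = 1, and sigma_e^2 at its prior mode kappa/(alpha+1).  The "random"
    strategy jitters the anchor with per-chain normal noise (sd 0.1 for
    log mu, 0.5 for efficiencies).
    """
    post = UnconstrainedPosterior(data, spec)
    z_mu = _naive_anchor_logmu(data)
    q = data.q
    if spec.covariate_adjusted:
        beta = np.concatenate([z_mu.mean(axis=0), np.zeros(q)])
    else:
        beta = z_mu.mean(axis=0)
    z_sig = np.zeros(q)
    hyper = spec.hyper
    z_se = float(np.log(hyper.kappa_sigma / (hyper.alpha_sigma + 1.0)))
    anchor = post.pack(z_mu, beta, z_sig, np.zeros(q), z_se)

    inits = []
    seeds = np.random.SeedSequence([mcmc.seed, 0xA11C]).spawn(mcmc.chains)
    for c in range(mcmc.chains):
        if mcmc.init_strategy == "naive_anchor":
            inits.append(anchor.copy())
        else:
            rng = np.random.default_rng(seeds[c])
            theta = anchor.copy()
            theta[post._slices["eta"]] += 0.1 * rng.standard_normal(data.n * q)
            theta[post._slices["beta"]] += 0.1 * rng.standard_normal(post.n_beta)
            theta[post._slices["z_sig"]] += 0.1 * rng.standard_normal(q)
            if post.varying:
                theta[post._slices["zeta"]] += 0.5 * rng.standard_normal(q)
            inits.append(theta)
    return inits


def fit(data: PairedDataset, spec: ModelSpec, mcmc: McmcConfig):
    """Sample the posterior by NUTS and return (draws, diagnostics).

    Identical (data, spec, mcmc) including the seed reproduce identical
    draws.  Sampling problems (divergences, tree-depth saturation) are
    reported in the diagnostics, never silently dropped.
    """
    if data.qobs < 1:
        raise ValueError("need at least one observed taxon")
    post = UnconstrainedPosterior(data, spec)
    inits = initialize_chains(data, spec, mcmc)
    n_retained = mcmc.retained_iters

    chain_seeds = np.random.SeedSequence([mcmc.seed, 0x5A3D]).spawn(mcmc.chains)
    results = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(chain_seeds[c])
        logger.info("sampling chain %d/%d", c + 1, mcmc.chains)
        try:
            res = sample_chain(
                post.logp_grad,
                inits[c],
                mcmc.warmup_iters,
                n_retained,
                rng,
                target_accept=mcmc.target_accept,
                max_treedepth=mcmc.max_treedepth,
                inv_mass0=post.initial_inv_mass(),
            )
        except Exception as err:  # noqa: BLE001 - surface with context
            raise RuntimeError(f"sampling failed in chain {c}: {err}") from err
        results.append(res)

    theta = np.concatenate([r.draws for r in results], axis=0)
    q = data.q
    nat = post.constrain(theta)
    mu, e = nat["mu"], nat["e"]
    beta, Sigma_diag = nat["beta"], nat["Sigma_diag"]
    sigma_e_sq = nat["sigma_e_sq"]

    if spec.centering != "soft" and post.varying:
        idx = range(data.qobs) if spec.centering == "hard_observed" else range(q)
        e = hard_center(e, list(idx))

    draws = PosteriorDraws(
        mu=mu,
        e=e,
        beta=beta,
        Sigma_diag=Sigma_diag,
        sigma_e_sq=sigma_e_sq,
        chain=np.repeat(np.arange(mcmc.chains), n_retained),
        spec=spec,
        config=mcmc,
    )
    diag = _diagnostics(draws, results, post)
    logger.info("done: %s", diag.summary())
    return draws, diag


def _group_rhat(by_chain_arr):
    """Classic split R-hat for every scalar in a (C, S, ...) array."""
    c, s = by_chain_arr.shape[:2]
    flat = by_chain_arr.reshape(c, s, -1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = np.array([gelman_rubin(flat[:, :, k]) for k in range(flat.shape[2])])
    return vals.reshape(by_chain_arr.shape[2:]) if by_chain_arr.ndim > 2 else vals


def _diagnostics(draws: PosteriorDraws, results, post) -> DiagnosticsReport:
    import arviz as az

    groups = {
        "mu": draws.by_chain(draws.mu),
        "beta": draws.by_chain(draws.beta),
        "Sigma_diag": draws.by_chain(draws.Sigma_diag),
    }
    if post.varying:
        groups["e"] = draws.by_chain(draws.e)
        groups["sigma_e_sq"] = draws.by_chain(draws.sigma_e_sq)

    rhat = {k: _group_rhat(v) for k, v in groups.items()}
    rhat_rn, ess = {}, {}
    for k, v in groups.items():
        da = v if v.ndim > 2 else v[:, :, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.convert_to_dataset(da)
            rhat_rn[k] = np.asarray(az.rhat(idata)["x"])
            ess[k] = np.asarray(az.ess(idata)["x"])

    mu_vals = np.ravel(rhat["mu"])
    mu_vals = mu_vals[np.isfinite(mu_vals)]
    q25, med, q75 = (
        np.percentile(mu_vals, [25, 50, 75]) if mu_vals.size else (np.nan,) * 3
    )
    return DiagnosticsReport(
        rhat=rhat,
        rhat_rank_normalized=rhat_rn,
        ess=ess,
        mu_rhat_median=float(med),
        mu_rhat_iqr=(float(q25), float(q75)),
        divergences=int(sum(r.divergences for r in results)),
        max_treedepth_hits=int(sum(r.max_treedepth_hits for r in results)),
        mean_accept=float(np.mean([r.mean_accept for r in results])),
    )
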