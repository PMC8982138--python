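"""Synthetic data generator for the joint abundance model.

Emulates the generative process used in the simulation study:

    beta_j    ~ N(0, beta_var)        (iid over taxa; default variance 50)
    log mu_i. ~ N_q(beta, Sigma)      (Sigma diagonal, identity by default)
    e_j       ~ Lognormal(0, sigma_e^2)   (e = 1 exactly when sigma_e = 0)
    M_i       ~ DiscreteUniform(M_low, M_high)   (default 1e4 .. 1e5)
    V_ij      ~ Poisson(mu_ij)            (realized for every taxon)
    W_i.      ~ Multinomial(M_i, p_i.),  p_ij = mu_ij e_j / sum_l mu_il e_l

Taxa whose true mean concentration (averaged over samples) falls below an
abundance floor (default 1 unit) are excluded from the analysis tables;
the ``qobs`` most abundant retained taxa by mean read count are designated
"observed" and their Poisson realizations form the concentration table.

One master seed spawns independent substreams for (beta, Sigma), e, mu,
M, V and W, so that e.g. changing ``sigma_e`` leaves the other draws
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ConcentrationTable, CountTable, PairedDataset

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_dataset",
    "simulate_paired",
    "abundance_filter",
    "select_observed",
]


@dataclass(frozen=True)
class SimulationConfig:
    q: int
    qobs: int
    n: int = 100
    sigma_e: float = 0.0
    beta_var: float = 50.0
    Sigma_diag: np.ndarray | None = None  # defaults to ones (identity)
    M_low: int = 10**4
    M_high: int = 10**5
    abundance_floor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.qobs > self.q:
            raise ValueError("qobs cannot exceed q")
        if self.M_low > self.M_high or self.M_low < 1:
            raise ValueError("require 1 <= M_low <= M_high")
        if self.sigma_e < 0 or self.beta_var < 0:
            raise ValueError("variance parameters must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (full q-taxon matrices)."""

    mu: np.ndarray  # (n, q)
    e: np.ndarray  # (q,)
    beta: np.ndarray  # (q,)
    Sigma_diag: np.ndarray  # (q,)
    M: np.ndarray  # (n,)
    V_full: np.ndarray  # (n, q) Poisson realizations for every taxon
    W_full: np.ndarray  # (n, q)
    retained_taxa: np.ndarray  # indices into 0..q-1 surviving the floor
    observed_taxa: np.ndarray  # indices into 0..q-1, subset of retained


def abundance_filter(mu: np.ndarray, floor: float) -> np.ndarray:
    """Indices of taxa whose mean true concentration is at least ``floor``."""
    return np.flatnonzero(np.asarray(mu).mean(axis=0) >= floor)


def select_observed(W: np.ndarray, qobs: int) -> np.ndarray:
    """The ``qobs`` taxa with the largest mean read counts.

    Returned in decreasing order of abundance; ties broken by column order
    (first column wins).
    """
    W = np.asarray(W)
    if qobs > W.shape[1]:
        raise ValueError(f"qobs={qobs} exceeds the number of taxa ({W.shape[1]})")
    means = W.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    return order[:qobs]


def simulate_dataset(cfg: SimulationConfig, beta: np.ndarray | None = None):
    """Generate one dataset; returns (truth, CountTable, ConcentrationTable).

    The count table holds the retained taxa (depths recomputed as retained
    row sums); the concentration table holds the Poisson realizations of
    the observed taxa.  Supplying ``beta`` holds the population fixed
    across replicates (the replicate-within-population design); by default
    beta is redrawn from N(0, beta_var) per call.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(6)
    r_pop, r_e, r_mu, r_m, r_v, r_w = (np.random.default_rng(s) for s in ss)
    n, q = cfg.n, cfg.q

    if beta is None:
        beta = r_pop.normal(0.0, np.sqrt(cfg.beta_var), size=q)
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (q,):
            raise ValueError("beta must have length q")
    Sigma_diag = (
        np.ones(q) if cfg.Sigma_diag is None else np.asarray(cfg.Sigma_diag, float)
    )
    e = np.exp(r_e.normal(0.0, cfg.sigma_e, size=q)) if cfg.sigma_e > 0 else np.ones(q)
    mu = np.exp(r_mu.normal(beta[None, :], np.sqrt(Sigma_diag)[None, :], size=(n, q)))
    M = r_m.integers(cfg.M_low, cfg.M_high, endpoint=True, size=n)
    V_full = r_v.poisson(mu)
    p = mu * e[None, :]
    p /= p.sum(axis=1, keepdims=True)
    W_full = np.vstack([r_w.multinomial(M[i], p[i]) for i in range(n)])

    retained = abundance_filter(mu, cfg.abundance_floor)
    if retained.size == 0:
        raise RuntimeError(
            "every taxon fell below the abundance floor; lower the floor or "
            "use a different seed"
        )
    if cfg.qobs > retained.size:
        raise RuntimeError(
            f"only {retained.size} taxa retained but qobs={cfg.qobs} requested"
        )
    observed = retained[select_observed(W_full[:, retained], cfg.qobs)]

    truth = SimulationTruth(
        mu=mu,
        e=e,
        beta=beta,
        Sigma_diag=Sigma_diag,
        M=M,
        V_full=V_full,
        W_full=W_full,
        retained_taxa=retained,
        observed_taxa=observed,
    )
    sample_ids = [f"sample_{i + 1:03d}" for i in range(n)]
    taxon_ids = [f"taxon_{j + 1:03d}" for j in range(q)]
    counts = CountTable(
        W_full[:, retained], sample_ids, [taxon_ids[j] for j in retained]
    )
    conc = ConcentrationTable(
        V_full[:, observed], sample_ids, [taxon_ids[j] for j in observed]
    )
    return truth, counts, conc


def simulate_paired(cfg: SimulationConfig, beta: np.ndarray | None = None):
    """As :func:`simulate_dataset` but aligned into a PairedDataset.

    Returns ``(truth, paired, mu_retained, V_retained)`` where the last
    two are the true concentrations and realized V for the retained taxa
    in the column order of the paired count table (observed taxa first).
    """
    truth, counts, conc = simulate_dataset(cfg, beta=beta)
    # Build the aligned pair directly (observed taxa first, remaining
    # retained taxa in ascending index order); qobs == q is legal here.
    obs_set = set(truth.observed_taxa.tolist())
    rest = [j for j in truth.retained_taxa if j not in obs_set]
    order = np.array(list(truth.observed_taxa) + rest, dtype=np.int64)
    taxon_ids = [f"taxon_{j + 1:03d}" for j in order]
    aligned_counts = CountTable(truth.W_full[:, order], counts.sample_ids, taxon_ids)
    paired = PairedDataset(aligned_counts, conc)
    return truth, paired, truth.mu[:, order], truth.V_full[:, order]
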