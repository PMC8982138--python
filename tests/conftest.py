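import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jointabund.data import ConcentrationTable, CountTable, PairedDataset

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_paired(W, V, covariates=None) -> PairedDataset:
    """Paired dataset with generated ids; observed taxa must come first."""
    W = np.asarray(W)
    V = np.asarray(V)
    n, q = W.shape
    samples = [f"s{i}" for i in range(n)]
    taxa = [f"t{j}" for j in range(q)]
    return PairedDataset(
        CountTable(W, samples, taxa),
        ConcentrationTable(V, samples, taxa[: V.shape[1]]),
        covariates,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_paired(rng):
    """Small random paired dataset with a mix of large and zero counts."""
    W = rng.integers(0, 300, size=(6, 4))
    W[:, 0] += 5  # keep every sample's observed block nonzero
    V = rng.integers(1, 60, size=(6, 2))
    return make_paired(W, V)


@pytest.fixture(scope="session")
def recovery_fit():
    """One moderately sized seeded fit shared across test modules.

    Simulated with varying efficiency (sigma_e = 0.5) and fit with the
    varying-efficiency model at short-chain settings.
    """
    from jointabund.estimators import BayesianAbundanceEstimator
    from jointabund.simulate import SimulationConfig, simulate_paired

    cfg = SimulationConfig(q=10, qobs=4, n=25, sigma_e=0.5, seed=14)
    truth, paired, mu_true, V_true = simulate_paired(cfg)
    est = BayesianAbundanceEstimator(
        chains=2, warmup=300, iters=550, seed=5
    ).fit(paired)
    return {
        "truth": truth,
        "paired": paired,
        "mu_true": mu_true,
        "V_true": V_true,
        "est": est,
    }
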