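# jointabund

Joint modeling of **relative** and **absolute** microbial abundances.

Microbiome surveys usually profile a community with a broad-range
sequencing assay (16S amplicon or shotgun reads), which yields counts
`W_ij` for every taxon but fixes only each taxon's *share* of the
community.  Absolute concentrations `V_ij` (e.g., 16S gene copies per
swab from taxon-specific qPCR) are available for only a handful of taxa
because each assay must be developed separately.  `jointabund` combines
the two to estimate the true concentration `mu_ij` of **every** taxon in
every sample — with credible intervals for `mu` and prediction intervals
for the unmeasured concentrations — while explicitly modeling the
taxon-specific *efficiency* `e_j` with which sequencing detects each
taxon relative to the concentration assay:

    V_ij | mu_ij         ~ Poisson(mu_ij)                      (j ≤ qobs)
    W_i· | M_i, mu_i·, e ~ Multinomial(M_i, p_i·),   p_ij = mu_ij e_j / Σ_l mu_il e_l

with a lognormal prior hierarchy (`log mu_i· ~ N_q(β, Σ)`,
`β_j ~ N(0, σ_β²)`, `Σ_jj ~ Lognormal(0, σ_Σ²)`,
`e_j ~ Lognormal(0, σ_e²)`, `σ_e² ~ InvGamma(α_σ, κ_σ)`), sampled by a
built-in No-U-Turn HMC sampler with analytic gradients.  Ignoring
efficiency variation biases concentration estimates and breaks interval
coverage; modeling it restores both.  The package also implements the
simple scaling-factor estimator `mu_hat_ij = s_i W_ij`
(`s_i = ΣV_i/ΣW_i` over the observed taxa) with delta-method intervals,
an equal-efficiency Bayesian variant, a synthetic-data generator
matching the simulation-study design, the performance metrics
(RMSE/RMSPE/coverage), and a leave-one-taxon-out validation.

Intended users: statisticians and computational microbiologists who have
a sequencing count table plus qPCR-style measurements for a subset of
taxa and want absolute abundances for everything, with honest
uncertainty.

## Worked example

```python
import numpy as np
from jointabund import BayesianAbundanceEstimator, NaiveScalingEstimator
from jointabund import SimulationConfig, simulate_paired

# a synthetic community: 20 taxa, concentrations observed for 5,
# detection efficiencies spread over roughly e^(+-1.6)
cfg = SimulationConfig(q=20, qobs=5, n=50, sigma_e=0.8, seed=5)
truth, paired, mu_true, V_true = simulate_paired(cfg)

est = BayesianAbundanceEstimator(chains=2, warmup=300, iters=550, seed=0)
est.fit(paired)                       # X = counts W, y = concentrations V
print(est.diagnostics_.summary())

ci = est.credible_intervals(0.05)     # for every (i, j), zeros included
print("mu coverage:", ci.contains(mu_true).mean().round(3))

naive = NaiveScalingEstimator().fit(paired.W, paired.V)
lo, hi = naive.confidence_intervals()
ok = ~np.isnan(lo)                    # no intervals where W_ij = 0
inside = (lo[ok] <= mu_true[ok]) & (mu_true[ok] <= hi[ok])
print("naive coverage (nonzero cells):", inside.mean().round(3),
      " zero cells:", (~ok).mean().round(2))
```

Output:

```
median R-hat(mu)=1.000 IQR=[0.998, 1.003], divergences=0, mean acceptance=0.83
mu coverage: 0.869
naive coverage (nonzero cells): 0.157  zero cells: 0.72
```

Read: with strongly varying efficiencies the joint model's nominal-95%
credible intervals cover the true concentrations for ~87% of
sample-taxon pairs even at these short single-replicate chain lengths
(≥95% at full settings, averaged over replicates), while the
scaling-factor estimator — which wrongly assumes equal efficiencies —
covers only ~16% of the pairs it can address at all, and 72% of pairs
have a zero count and get no interval.
`est.prediction_intervals()` returns point predictions and zero-truncated
Wald intervals for the concentrations of the 15 unmeasured taxa.

## Command line

```bash
jointabund simulate --q 40 --qobs 7 --n 100 --sigma-e 0.8 --seed 1 --out sim/
jointabund fit --w-table sim/W.csv --v-table sim/V.csv \
    --model varying --chains 4 --warmup 1000 --iters 1500 --seed 1 --out fit/
```

`fit` writes posterior summaries for `mu` and the efficiencies,
convergence diagnostics, prediction intervals for unmeasured taxa, and a
manifest with the resolved configuration; every run is reproducible from
its manifest and seed.

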