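# Methods

## The estimation problem

Broad-range sequencing assays (16S amplicon, shotgun) report how many
reads each microbial taxon received, which fixes only the *relative*
abundance of each taxon in a sample.  Taxon-specific assays such as qPCR
measure *absolute* concentration (e.g., 16S gene copies per swab) but are
expensive to develop, so they typically exist for only a handful of taxa.
`jointabund` estimates the concentration of **every** sequenced taxon by
jointly modeling both data types, and crucially accounts for the fact
that sequencing detects different taxa with different efficiencies: the
read share of a taxon is proportional to its concentration with a
taxon-specific slope, not a common one.

## Data model

For sample i = 1..n and taxon j = 1..q, with concentrations observed for
the first `qobs` taxa:

    V_ij | mu_ij          ~ Poisson(mu_ij),                    j <= qobs
    W_i. | M_i, mu_i., e  ~ Multinomial(M_i, p_i.),
                            p_ij = mu_ij e_j / sum_l mu_il e_l

`mu_ij` is the true concentration, `e_j` the detection efficiency of the
sequencing assay for taxon j relative to the concentration assay, and
`M_i = sum_j W_ij` the read depth.  The observed concentration `V_ij` is
a noisy realization: a zero measurement does not imply absence.

Priors:

    log mu_i. ~ N_q(beta, Sigma)          Sigma diagonal
    beta_j    ~ N(0, sigma_beta^2)
    Sigma_jj  ~ Lognormal(0, sigma_Sigma^2)
    e_j       ~ Lognormal(0, sigma_e^2)
    sigma_e^2 ~ InverseGamma(alpha_sigma, kappa_sigma)

`Lognormal(0, s^2)` places variance `s^2` on the log; the inverse gamma
uses the shape–scale density proportional to `x^(-a-1) exp(-k/x)` (the
parameterization is stated because results are mildly sensitive to it).
With a per-sample covariate x_i the prior mean becomes
`beta0 + beta1 * x_i` with independent normal priors on both coefficient
vectors.

Efficiencies are identified only up to a common multiplicative constant;
the zero-mean prior on `log e` *soft-centers* them.  Hard centering
(dividing draws by the geometric mean of `e` over the observed taxa, or
over all taxa) is available as a deterministic post-sampling transform;
soft centering is the default, and in practice the posterior mean of
`mean_j log e_j` sits near zero.

Two simpler estimators are included for comparison:

* the **scaling-factor (naive) estimator**
  `mu_hat_ij = s_i W_ij`, `s_i = sum_j<=qobs V_ij / sum_j<=qobs W_ij`,
  with delta-method intervals on the log scale.  Its variance estimate is
  `1/T_V + 1/W_ij -/+ 1/T_W` (minus for observed taxa, which are part of
  the observed read total T_W; plus for unobserved taxa, where the
  multinomial covariance flips the sign).  Intervals exist only where
  `W_ij > 0`;
* the **efficiency-naive Bayesian model**, the same hierarchy with every
  `e_j` fixed at 1.  It demonstrates what goes wrong when real
  efficiency variation is ignored: its credible intervals undercover as
  the spread of efficiencies grows.

## Default hyperparameters

| parameter | default | meaning |
| --- | --- | --- |
| `sigma_beta_sq` | 50 | prior variance of the taxon-level mean log concentration; matches log-concentration data whose sample variance is near 50 (typical for qPCR copies per swab) |
| `sigma_Sigma_sq` | 50 | prior log-variance of `Sigma_jj` |
| `alpha_sigma`, `kappa_sigma` | 2, 1 | inverse-gamma prior on `sigma_e^2`; proper but diffuse, prior mode 1/3 |
| `sigma_beta0_sq`, `sigma_beta1_sq` | 1.62², 1² | covariate-model coefficient priors |
| `alpha` | 0.05 | interval level 1 − alpha |

These defaults assume concentrations on a natural-log scale whose
variance is of order 50; rescale them for data measured in other units.

## Posterior computation

Sampling uses a self-contained No-U-Turn Hamiltonian Monte Carlo sampler
(recursive tree doubling with a slice variable, dual-averaging step-size
adaptation to a 0.8 target acceptance, Stan-style expanding-window
estimation of a diagonal mass matrix) with analytic gradients of the log
posterior.  Gradients are evaluated by a numba-compiled kernel; a NumPy
reference implementation is kept and the two are asserted equal in the
test suite.

The posterior geometry is poor in the natural parameterization, so the
sampler works in transformed coordinates.  All transforms are exact
bijections with their Jacobians included, so the posterior is unchanged:

1. **Log transforms** for positive parameters (`Sigma_jj`, `sigma_e^2`).
2. **Read-scale coordinates.**  For a column where the read total
   dominates the concentration total (always true for taxa with no
   concentration data), the sampler uses `a_ij = log mu_ij + log e_j`
   and `beta'_j = beta_j + log e_j`.  The tight multinomial constraint
   (precision ~ W_ij) then involves `a_ij` alone, and the shared
   `log e_j` appears only in the looser Poisson/prior terms.  Without
   this, each efficiency sits on an n-way ridge with its whole column of
   concentrations and the chain crawls.  A side effect matches the
   statistics: the efficiency of a taxon never measured by the
   concentration assay is driven by its prior, as it should be.
3. **Per-cell centering.**  A log-concentration coordinate is sampled on
   its natural scale where the likelihood pins it down (cell count
   ≥ 10) and as a standardized residual of its prior otherwise — the
   usual centered/non-centered trade-off decided cell by cell from the
   data.
4. **Curvature preconditioning.**  The initial diagonal mass is the
   reciprocal of a Fisher-information approximation built from the
   counts (`W_ij + V_ij` per cell), so cells whose counts are ~10^6 do
   not stall the warmup that must otherwise discover those scales.

Chains are initialized at the scaling-factor estimate
(`log(s_i W_ij + 0.5)`, with a global scaling fallback for samples with
no observed reads), `e = 1`, `Sigma_jj = 1`, `beta` at column means, and
`sigma_e^2` at its prior mode; the default strategy jitters this anchor
per chain (sd 0.1, efficiencies 0.5).  A deterministic un-jittered
anchor initialization is available.

One soft direction remains by construction: the common scale of the
observed-taxa efficiencies is constrained only by the soft-centering
prior, so that one-dimensional mode mixes more slowly than the rest.
Divergent trajectories and tree-depth saturation are counted and
reported in the diagnostics; convergence is summarized by the classic
split-chain Gelman–Rubin statistic (median and IQR over all mu entries),
with rank-normalized R-hat and effective sample sizes from `arviz`
reported alongside as an independent implementation.

Default sampler settings are desk-scale: 4 chains, 1000 warmup and 500
retained iterations each.  The full-scale settings used for the
published simulation study (10,000 warmup / 10,500 total) are available
through `McmcConfig`; they change runtimes from minutes to hours without
changing any interface.

## Intervals

* **Credible intervals for mu**: equal-tailed empirical posterior
  quantiles (linear interpolation of order statistics — stated so
  oracles can match exactly).  These exist for every sample and taxon,
  including pairs with a zero read count — a structural advantage over
  the scaling-factor estimator.
* **Prediction intervals for unobserved V**: Wald-type,
  `max(0, mu_hat ± z sqrt(mu_hat + Var(mu)))`, from the iterated-variance
  identity for a Poisson observable, truncated at zero; or
  posterior-predictive quantile intervals (one Poisson draw per
  posterior mu draw).  The two constructions agree closely in practice;
  Wald is the default, the point prediction is the posterior mean
  (median by option).

## Synthetic data generator

`simulate_dataset` reproduces the simulation-study process: `beta_j ~
N(0, 50)` (iid, redrawn per replicate by default; a fixed population
beta can be supplied to emulate the replicate-within-population design),
`Sigma = I`, `log mu_i. ~ N(beta, Sigma)`, `e_j ~ Lognormal(0,
sigma_e^2)` with `e = 1` exactly at `sigma_e = 0`, `M_i ~
DiscreteUniform(1e4, 1e5)`, `V ~ Poisson(mu)` for every taxon, and
multinomial reads.  Taxa whose true mean concentration falls below 1 are
excluded from the analysis tables (real-data workflows must filter on
observed counts instead — `prevalence_filter` — because mu is unknown);
the `qobs` most abundant retained taxa by mean read count are designated
observed, ties broken by column order.  One master seed spawns
independent substreams for the population draw, efficiencies,
concentrations, depths, realized concentrations and reads, so varying
`sigma_e` perturbs nothing else.

What the generator does *not* emulate: taxon–taxon correlation
(`Sigma` is diagonal), overdispersion beyond Poisson/multinomial,
batch-dependent efficiencies, or missing concentration measurements.
Calibration results on this synthetic process therefore say nothing
about robustness to those features; the model's own robustness to
misspecifying the efficiency distribution is not tested here.

A note on one published summary: the fraction of sample-taxon pairs
with zero reads depends strongly on the single `beta` draw when the
population is held fixed across replicates.  With `beta` redrawn per
replicate the expected fractions at q = 10/20/40/60 are roughly
13/31/45/54%; under a fixed population draw the realized value at small
q can be anywhere from 0% to ~40% depending on the seed.  The large-q
values are stable across both designs; the small-q values are not
reproducible in expectation and should be read as realizations.

## Evaluation conventions

RMSE for mu and RMSPE for V are computed on the raw concentration scale,
averaged over all retained sample-taxon pairs (RMSE) or the unobserved
block (RMSPE); a log-scale option exists because raw-scale error is
dominated by the most abundant taxa.  Coverage uses closed intervals.
Pairs with a zero scaling-factor estimate are excluded from naive
coverage only.  The leave-one-taxon-out validation restricts the data to
the observed subcomposition, withholds each concentration column in
turn, refits, and scores prediction-interval coverage and MSPE against
the withheld column; fold seeds derive from the master seed plus the
taxon index, so folds are order-independent.

## Problem sizes used by the test suite

The published simulation study ran on a cluster (50 replicates per
setting at n = 100 with four 10,500-iteration chains per fit).  The
package's own checks use reduced scales chosen as the smallest designs
that still separate the estimators cleanly: coverage comparisons use
B = 10 replicates at n = 50 (q = 20, qobs = 5, sigma_e = 0.8 for the
varying-efficiency contrast; q = 10, sigma_e = 0 for the calibration
check) with 2 chains of 300 warmup / 150 retained iterations; the
end-to-end recovery check uses one seeded n = 30, q = 10, qobs = 5
dataset at the default desk-scale sampler settings.  The zero-fraction
study needs no model fitting and runs at the original scale (B = 50,
n = 100).

## Known limitations

* Runtime grows quickly with n and q; the published full-scale settings
  are hours per fit.  The sampler is single-threaded.
* The common scale of observed efficiencies mixes slowly (prior-limited
  by design); efficiency summaries for individual taxa are reliable,
  their common level less so at short chain lengths.
* Concentration data must be complete for the observed taxa; missing
  `V` entries are rejected rather than imputed.
* Batch-dependent efficiencies are an extension point, not implemented:
  the natural extension models `e_jk ~ Lognormal(xi_j, sigma_xi^2)` with
  a taxon-level `xi_j ~ Lognormal(0, sigma_e^2)`, which adds one level
  to the hierarchy and one index to the efficiency term of the density.
* Negative-binomial or Dirichlet-multinomial observation models are out
  of scope.
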