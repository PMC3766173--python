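# Methods

## Model and estimation

Expression is modelled on the log scale. All matrices are centered per
gene before network fitting (means removed, variances deliberately left
unscaled: the magnitude of log-fold variation is biologically meaningful
and is what is assumed to transfer across array platforms). The
simultaneous-equations model Y = BY + E (zero-diagonal B, Gaussian
errors) is estimated one gene at a time by ridge regression of y_g on
all other genes with one penalty λ shared across genes. A single global
λ keeps the selection problem one-dimensional and avoids tuning and
testing on the same data.

### Solvers

Two interchangeable solvers are implemented and tested against each
other:

* **primal** — per gene, solve the (G−1)×(G−1) system
  (X′X + λI)β = X′y after deleting the gene's own row. Used when
  samples outnumber genes; also the oracle in tests.
* **dual with Gram downdate** — compute S = Y′Y (N×N) and
  M = (S + λI)⁻¹ once over *all* genes; per gene, remove the gene's own
  rank-one contribution y_g y_g′ from S by Sherman–Morrison:
  α_g = M y_g / (1 − y_g′ M y_g), then map back, β_gj = y_j·α_g
  (self-entry zeroed). Since S − y_g y_g′ ⪰ 0 and λ > 0, the
  denominator is strictly positive. Cost O(G·N² + G²·N), which makes
  thousand-gene networks practical on one core.

Degenerate inputs: λ ≤ 0 is rejected (identifiability requires λ > 0);
zero-variance genes become all-zero rows after centering, so they
receive a zero coefficient row and zero weight as predictors — they are
flagged by `zero_variance_genes` rather than dropped, preserving matrix
alignment. Missing values are rejected at construction.

### Penalty selection

`select_lambda` performs one seeded half-split of the database samples
(the single-split design keeps the procedure cheap and mirrors how such
compendia are actually partitioned). Each half is re-centered. Three
diagnostics are computed per candidate λ:

1. out-sample prediction: per-gene Pearson correlation between
   half-1-trained predictions and half-2 observations, summarised by
   the median (mean/max selectable); genes with zero out-sample
   variance are skipped;
2. coefficient stability: mean per-gene correlation of the two half
   fits' coefficient vectors;
3. optionally, median correlation of full-database predictions with an
   independent target experiment.

The chosen λ maximises (1); (2) and (3) are reported for inspection
only, because only (1) has a natural argmax and it is the quantity the
method ultimately needs (transferable prediction). Ties prefer the
smallest λ (less bias).

### Over-shrinkage correction

In the target experiment, ν_g is the no-intercept OLS slope of the
centered y_g on its network predictor; its standard error uses N−1
residual degrees of freedom. Scaling a network row by c > 0 rescales
ν̂_g by 1/c and leaves the fitted values invariant, so the arbitrary
shrinkage scale cancels exactly — this invariance is enforced by test.
When the predictor is uncorrelated with the target data, ν̂_g is
centered at 0 and the network's influence vanishes.

## Testing

* **Differential expression** (`fit_de_gene`): OLS of y_g on
  [1, Y_Ng, x] with a two-sided Wald t-test on δ_g (residual df). With
  the network term absent and no pairing this is *algebraically* the
  pooled-variance two-sample t-test, the naive comparator. A constant
  predictor triggers the naive fallback with a `degenerate` flag, so
  full tables are always produced.
* **Paired designs**: `pairing="fixed"` adds per-pair intercepts;
  `pairing="random"` fits a per-pair random intercept by REML
  (statsmodels MixedLM) with Wald t-tests on
  N − (#fixed effects) − (#pairs) degrees of freedom. When the pair
  variance component collapses to the zero boundary (or the fit fails)
  the model is refit as plain OLS — the boundary case is exactly where
  the random intercept carries no information.
* **Network disruption** (`fit_interaction_gene`): adds the elementwise
  (Y_Ng × x) column; rank-deficient designs (e.g. a predictor constant
  within one condition) are flagged degenerate and reported from the
  no-interaction fit instead of crashing.
* **Rhythms** (`fit_cosinor`): a·cos(T + b) is linearised on the
  (cos T, sin T) basis; a = √(α² + β²) ≥ 0 and b = atan2(β, α) ∈ (−π, π].
  H₀: a = b = 0 uses the 2-df likelihood-ratio statistic
  n·log(RSS₀/RSS₁). Its asymptotic χ²(2) reference is measurably
  anticonservative at circadian sample sizes (≈6.7% rejection at
  nominal 5% with n = 24), so the default p-value uses the exact
  finite-sample null of the same statistic — its monotone F(2, n−k)
  transform under Gaussian errors; the χ² reference remains available.
  The null model retains the network term when present, so the test
  isolates the time dependence. The period is fixed (times are supplied
  in radians); genotype/condition labels are deliberately not used.
* **Multiplicity**: Benjamini–Hochberg by default; Storey's q-value
  with π₀ estimated at λ = 0.5 as an option.

## Calibration tools

The BUM density f(p) = π + (1−π)·a·p^(a−1) (0 < a < 1) is fitted by
maximum likelihood with L-BFGS-B on logit-transformed parameters from a
deterministic grid of 5 starts; the pure-uniform boundary is always a
candidate, so the fitted log-likelihood never falls below the uniform
model's. Exact zeros are clamped to 1e−12 with a warning (the density
is unbounded at 0). π/f(p), clipped to [0, 1], is the empirical-Bayes
false-positive rate at p.

Permutation nulls re-run the complete per-gene test under relabelled
conditions: free permutations for unpaired designs; for paired designs,
within-pair swaps only (the exchangeable relabellings), enumerated
exhaustively when 2^#pairs ≤ n_perm and otherwise sampled without
replacement. Default 100 permutations; fully seeded and bit-reproducible.

## Synthetic data

`compound_symmetric_blocks` draws each block as
√ρ·f + √(1−ρ)·e (shared factor f, idiosyncratic e), realising
unit-variance compound symmetry exactly. Two designs are generated:

* **Study 1** — one continuous outcome, two independent blocks of 100
  predictors (ρ = 0.9), N = 201, within-block effects +1 and −1, unit
  noise. Used to demonstrate coefficient equalisation and scale
  recovery under λ = 10⁴.
* **Study 2** — database G = 200 × N_D = 100 and an independent
  experiment N = 20 (10 control / 10 treated) sharing the block
  structure (ρ = 0.8); each gene is DE with probability 0.2, with
  δ = ±1 (fair-coin sign) added to treated samples. One master seed
  spawns child streams for database, experiment and truth.

What the generators emulate: dense block co-expression, platform-free
log-scale data, additive condition effects. What they do not: heavy
tails, mean–variance coupling, probe-level noise, batch structure,
scale-free network topology, or database/experiment platform shifts.
Passing tests therefore demonstrate correctness of the estimators and
their claimed statistical behaviour under the stated Gaussian designs,
not performance on any particular real platform.

A known behaviour worth stating: in study 2, a gene that is *marginally*
non-DE but whose network-mates are DE acquires a small conditional mean
shift through the network predictor (−ν·Σ_j B_gj δ_j). The
network-conditional null is therefore not identical to the marginal
null, and non-DE p-values are slightly sub-uniform in runs with many DE
genes — with de_prob = 0 the tests are exactly calibrated. This is the
price of testing "differential expression conditional on the network",
which is a deliberately different hypothesis from the marginal one.

## Problem sizes and numerics

Simulation-backed tests use the study designs above at their stated
sizes, with 20 replicates for power/calibration comparisons, 50 seeds
for recovery means, and 1000–4000 draws for type-I checks — sizes at
which the Monte Carlo error is far below the asserted tolerances.
Solver agreement is asserted at 1e−8 relative, scale invariances at
1e−10, and the t-test reduction at 1e−12 (it is exact algebra).
Correlations are Pearson on centered vectors; constant vectors yield
NaN and are skipped in medians. All result files are plain text with
`%.12g` formatting, which is what makes seeded reruns byte-identical.

## Limitations

* The random-intercept Wald test uses residual degrees of freedom, not
  a Satterthwaite approximation; with very few pairs its p-values are
  approximate.
* One global λ is a modelling choice, not an optimum per gene;
  gene-specific penalties are out of scope.
* The network is a dense ridge fit: no sparsity, thresholding, or
  structure learning on B is attempted, and a single network is used
  per analysis (no multi-network combination).
* BUM fitting assumes p-values in (0, 1] from two-sided continuous
  tests; heavily discrete p-values would violate the mixture shape.
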