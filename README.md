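# osrr — network-adjusted differential expression by over-shrinkage ridge regression

Small expression experiments (N ≈ 10–20 arrays) rarely have the power to
separate a perturbation's direct effect on a gene from the correlated
drift of the whole transcriptome. `osrr` addresses this by borrowing a
gene co-expression network from a large, independent expression
*database* and using it as a per-gene covariate in the small
experiment's tests. It is aimed at analysts working with bulk
transcriptomics (microarray or log-scale RNA-seq summaries) who have
access to a related compendium — e.g. a chromosomal-deletion case-control
study leaning on a few hundred public arrays of the same cell type.

## The model

Write the experiment as a G × N log-expression matrix Y with rows y_g,
and the database as Y_D (G × N_D, N_D ≫ N). Expression follows the
simultaneous-equations model Y = BY + E with zero-diagonal B: each gene
is a weighted sum of all the others. The workflow is two-stage:

1. **Network fit (database).** For every gene g, ridge regression with a
   single shared penalty λ:

       β̂_Dg = argmin ‖y_Dg − β Y_D,−g‖² + λ‖β‖²

   λ is chosen from {10², …, 10⁶} by split-sample out-of-sample
   prediction. Deliberately heavy penalties are preferred: they
   *equalise* the weights of correlated predictors (a robust,
   KNN-like averaging), at the price of shrinking the prediction scale.

2. **Over-shrinkage correction and testing (experiment).** The network
   predictor Y_Ng = β̂_Dg Y enters the per-gene linear model

       y_g = Y_Ng ν_g + X′δ_g + ε,

   where X is the condition indicator. The scalar ν_g, estimated
   jointly with δ_g, undoes the shrinkage bias of stage 1 — and shrinks
   the network's influence to zero when the database does not transfer
   (ν̂_g → 0). H₀: δ_g = 0 is differential expression *conditional on
   the network*. An optional interaction term (Y_Ng × X)γ_g tests
   condition-dependent rewiring, and a cosinor variant
   y_g = Y_Ng ν_g + a_g cos(T + b_g) + d + ε detects rhythms in
   time-course data. Dropping the network term recovers the classical
   pooled-variance t-test. p-value histograms can be calibrated with a
   beta-uniform mixture (BUM) and label-permutation nulls.

The G × G fit uses the dual (sample-space) form of ridge with a
Sherman–Morrison downdate of the shared Gram matrix, so the whole
network costs O(G·N_D²) instead of O(G⁴).

## Worked example

```python
import osrr

study = osrr.simulate_de_study(seed=3)          # G=200, N_db=100, N=20, 20% DE
db = osrr.center_genes(study.database)

report = osrr.select_lambda(db, seed=0)
print(report.pred_corr, report.chosen)
# [0.898, 0.898, 0.890, 0.886, 0.885] -> chosen lambda = 1000.0

model = osrr.fit_network(db, report.chosen)
pred = osrr.predict_network(model, osrr.center_genes(study.experiment))
osrr_tab = osrr.run_de_analysis(study.experiment, pred, study.covariates)
naive_tab = osrr.run_de_analysis(study.experiment, None, study.covariates)
print(osrr.evaluate_methods({"osrr": osrr_tab, "naive": naive_tab}, study.truth))
```

which prints (power / type-I error at p < 0.05, and the KS distance of
the non-DE p-values from uniform):

```
method  power_0.05  type1_0.05  ks_null
  osrr       1.000       0.067    0.081
 naive       0.714       0.000    0.276
```

The network-adjusted test finds every planted effect where the t-test
finds 71%, while its null p-values are far closer to uniform (the
t-test's nulls are badly non-uniform because of the ρ = 0.8 co-expression,
visible in its KS distance of 0.28). The mean rescaling coefficient here
is ν̄ ≈ 1.14: the network transfers, and stage 2 has undone the ridge
shrinkage. Fitting the BUM to the OSRR p-values gives a uniform weight
of 0.69 — an empirical-Bayes estimate that ~31% of genes carry signal,
matching the 20% planted DE plus network-transferred shifts.

The same pipeline is scriptable from the shell (`osrr simulate`,
`osrr select-lambda`, `osrr fit-network`, `osrr predict`, `osrr diffex`,
`osrr interaction`, `osrr cosinor`, `osrr bum`, `osrr permute`,
`osrr evaluate`); every stage writes a manifest and is byte-reproducible
for a fixed seed.

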