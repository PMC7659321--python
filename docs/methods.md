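# Methods

This note documents the models, parameter choices and known limitations
of recmet. Nothing here is an empirical claim beyond what the test suite
and `scripts/acceptance.py` compute.

## Synthetic data model

The generator produces a genes × samples log2-scale expression matrix
under a linear latent-factor model. For gene *g* in module *m(g)* and
sample *s*:

```
x[g, s] = mu[g] + λ[g] · F[m(g), s] + b[batch(s)] + ε[g, s]
```

with one standard-normal factor per module per sample, loading
`λ = module_signal` for module members and 0 for background genes,
baseline `mu ~ U(2, 8)`, additive per-batch shift `b ~ N(0, batch_shift_sd²)`
shared by every gene of a sample, and `ε ~ N(0, noise_sd²)`. The expected
within-module correlation is `λ² / (λ² + noise_sd²)` (0.69 at the default
λ = 1.5, noise 1), which is the regime in which correlation-network module
detection and guilt-by-association transfer of pathway annotation are
provably recoverable — this is the co-expression assumption the whole
method rests on, stated as a generative model.

Defaults (the "standard fixture", used by the acceptance script and the
pipeline-level tests): 600 genes, 3 modules of 100, 150 samples in 4
batches (`batch_shift_sd` 0.5), 60 receptors of which 40% are metabolic
and all planted in module 1. Of the nonmetabolic receptors, ~40% sit in
module 2 and are emitted as the known-negative list — they play the role
an independent negative receptor family (e.g. cytokine receptors, which
cluster in their own immune module on real data) plays in practice — ~30%
sit in module 3 and the rest among background genes (the latter end up in
no module and drop out of the feature space, mirroring the real-data loss
of seed positives to unclustered genes). 30 pathways of 10–50 genes: two
per module drawn with purity 0.8 from their target module, the rest
uniformly from all genes so they survive universe restriction as null
features. Seed positives are one third of the metabolic receptors; the
verification accept-list contains the seeds plus a random half of the
remaining metabolic receptors, standing in for manual literature
verification and deliberately leaving a nonempty unlabeled metabolic pool
for the consensus-prediction stage. Sample covariates (ischemic time
uniform on [0, 1500) min, age 20–79, sex, death class 90% ventilator) are
independent of expression; only the batch shift is a planted confounder.

What the generator does **not** emulate: count noise and the
mean–variance relation of RNA-seq, covariate-correlated expression
(age/sex effects), overlapping or hierarchically nested modules, hub-gene
degree heterogeneity inside modules, and realistic pathway overlap
structure. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the model's own assumptions, not
field performance on real tissue data.

## Preprocessing

- Log scale: values are treated as `log2(x + 1)`; the pseudocount is
  configurable. The expression filter operates on the raw scale
  (`x ≥ min_value` in `≥ min_fraction` of samples ⇔
  `log2(x + pseudocount)` threshold on stored values).
- Outlier samples: "standardized distance" is implemented as the z-score
  of each sample's mean Pearson correlation with all other samples (the
  standard sample-network connectivity approach); a Euclidean variant is
  available via `metric='euclidean'`. A zero-variance score vector yields
  no outliers.
- Quantile normalization maps every sample onto the across-sample mean of
  sorted value vectors; ties get the mean of the reference values at
  their averaged rank positions. Note a desk-scale artifact: with half of
  all genes in coherent modules, forcing a common per-sample distribution
  redistributes a little module signal into background genes (background
  mean |corr| rises from ~0.07 to ~0.15 on the standard fixture). This
  does not affect module recovery and shrinks as the module fraction
  shrinks, which is the real-data regime.
- Factor adjustment is a per-gene, per-level location-scale correction:
  within each level of the current factor, values are recentered to the
  gene's grand mean and rescaled so the within-level SD equals the pooled
  residual SD. Factors are adjusted iteratively in the order batch,
  ischemic bin, sex, age decade. Singleton levels are removed, genes with
  zero within-level variance dropped, single-level factors skipped with a
  warning. No empirical-Bayes shrinkage across genes is applied: in the
  synthetic regime (additive shifts, many samples per level) the
  location-scale correction removes the planted effect exactly, which is
  the property the tests verify. Because later factors re-perturb earlier
  ones slightly, exact mean equality holds only for the last factor
  adjusted; the planted batch effect itself is removed up to a global
  constant (verified against a shift-free twin dataset).
- Ischemic time bins: `min(5, ⌊t/300⌋ + 1)`; age decades labeled
  `"30-39"` etc.; analysis restricted to the ventilator death group by
  default.

## Network construction

- Biweight midcorrelation with per-gene weights
  `w_i = (1 − u_i²)² · 1[|u_i| < 1]`, `u_i = (x_i − median) / (9 · MAD)`;
  genes with MAD = 0 fall back to Pearson deviations; fully constant
  genes are an error (they are filtered upstream). Medians/MADs use the
  numpy midpoint convention for ties.
- Signed adjacency `a_ij = (0.5(1 + cor))^β` with β = 12 fixed; the
  scale-free log-log degree fit R² is exposed as a diagnostic
  (`scale_free_fit_r2`) but never auto-selects β.
- TOM as in the standard formulation; the implementation is matrix-based
  and is tested against a brute-force triple-loop oracle at 1e-12.
- Module detection: average-linkage clustering of `1 − TOM`, **static**
  cut at height 0.995, minimum module size 30, then iterative merging of
  module pairs whose eigengene dissimilarity `1 − cor` is below 0.25
  (closest pair first, eigengenes recomputed after each merge). Labels
  are renumbered by decreasing size, ties by original label; label 0
  marks unassigned genes, and receptors with label 0 are excluded from
  classification. Dynamic-hybrid tree cutting is deliberately out of
  scope: the static cut is parameter-explicit and deterministic, and
  recovers planted modules at the fixture's signal strength (ARI ≈ 1).
- Eigengene: first right-singular vector of the gene-standardized module
  submatrix, unit norm, sign-oriented to correlate positively with the
  mean member profile. Single-gene modules use the gene's standardized
  profile.

## Enrichment features

One-sided (upper-tail) hypergeometric test — the standard
over-representation statistic — per module × pathway, BH-adjusted within
each module across its pathways (matching per-gene-list adjustment of
common enrichment tools, not a global adjustment). The universe defaults
to all module-assigned genes and is configurable; it is recorded with the
output because p-values depend on it. Feature values are
`−log10(p_adj)` gated at `p_adj < 0.05`, zero otherwise, so all receptors
of a module share one row. Consequences worth knowing: the classifier
operates on module-level information only, and the smallest meaningful
unit of generalization is the module, not the gene.

## PU bagging

The OOB "score" is the binary classification vote (rate = positive votes
/ OOB appearances); averaging the SVM decision margin instead is
available via `score='margin'`. Bootstrap size k defaults to the number
of seed positives; the base SVM cost is fixed at 1 inside the bagging
loop (hyperparameter tuning happens only for the final classifiers). A
rate is thresholded only after at least `min_oob = 10` OOB appearances
(of t = 100 rounds) to avoid labels supported by one or two votes. The
negative rate is read as `1 − positive rate`. Candidate positives must
additionally pass the accept-list, the reproducible stand-in for manual
verification; passing `accept_list=None` accepts the raw expansion.

## Classification and metrics

- 10-fold CV uses a seeded, unstratified random partition (stratification
  available); a partition with a single-class training fold is redrawn
  with an incremented seed and logged. Confusion counts are summed over
  test folds, so class totals are conserved exactly.
- Metric variants: `variant='paper'` uses sensitivity TP/(TP+FN) and
  specificity TN/(TN+FN) — the pair of formulas that reproduces the
  reference results table exactly at 2-decimal rounding — while
  `variant='standard'` uses the conventional specificity TN/(TN+FP).
  Accuracy and MCC are identical between variants; MCC equals the phi
  coefficient of the binary truth/prediction vectors (tested
  exhaustively on small tables).
- Hyperparameters are tuned once globally, not nested per fold (a
  possible optimistic bias at real-data scale; at the fixture's
  separability it is immaterial). k-NN takes the **largest** k in 1–10
  with minimal CV error, capped at the smallest training-fold size; SVM
  cost takes the smallest grid value (2⁻⁵…2⁵) attaining minimal error,
  preferring the larger margin.
- k-NN vote ties resolve toward the negative class; distance ties resolve
  by row order (deterministic for a fixed feature matrix). Final models
  are refit on all labeled data; the consensus prediction is the
  intersection of the four models' positive sets, with per-receptor vote
  counts reported.

## Problem sizes

The standard fixture (600 genes × 150 samples, 60 receptors, 30
pathways) runs the full pipeline in a few seconds and is the size used by
the pipeline-level tests and the acceptance script; the same code paths
scale to tens of thousands of genes limited mainly by the O(n²) memory of
the correlation/TOM matrices (no block-wise computation is implemented).

## Known limitations

- Static-height tree cut, not dynamic-hybrid: very unequal module sizes
  or nested structure may need manual `cut_height` tuning.
- Location-scale factor adjustment assumes additive/scaling batch
  effects on a categorical design; it is not an empirical-Bayes method
  and will overfit levels with very few samples.
- Identical feature rows within a module make within-module ranking of
  receptors impossible by construction; kME is the tie-breaking signal a
  user should consult.
- The PU rate is a vote frequency, not a calibrated probability.
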