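# Methods

## Problem and data model

The package predicts binary platinum-chemotherapy response
(chemo-resistant = recurrence within 6 months = positive class) of
high-grade serous ovarian carcinoma samples from bulk RNA-seq TPM
profiles, in a multi-cohort setting where cohorts differ in ancestry,
center and class balance. All statistics and models operate on
log2(TPM + 1): TPM is within-sample normalized, and the log transform
stabilizes the heavy right tail of expression values. Raw-scale
analysis is available via a flag but is not the default.

## Synthetic-data generator

`resistseq.simulate` draws, for each cohort c, sample i and gene g,

    log2(TPM + 1) ~ Normal(mu + b_c + delta_{g,c} * 1[i resistant], sigma),

truncated below at 0 before back-transforming to TPM = 2^v − 1.

* `base_mean` (mu, default 5.0 log2 units): a mid-range expressed gene
  (~31 TPM); keeps the 0-truncation rare so the planted effects are not
  distorted.
* `batch_shift` (b_c, defaults 0, +0.5, −0.5): an additive
  cohort-constant on all genes, a minimal stand-in for cohort
  composition differences. The defaults are free parameters of the
  generator, not estimates of any real cohort.
* `effect_size` (delta, default 2.0 log2-fold): planted class effect,
  applied to shared genes in every cohort and to cohort-specific genes
  in their own cohort only. Gene roles are disjoint by construction.
* `noise_sd` (sigma, default 1.0 log2 units): within-class spread,
  a typical magnitude for log-scale bulk RNA-seq.
* Default cohort sizes mirror the study geometry this pipeline targets:
  149/59, 24/16 and 14/72 resistant/sensitive.

One `numpy` generator seeded from `seed` is consumed in
(cohort, sample, gene) order, so output is bit-identical across runs and
independent of any parallelism.

What the generator does **not** emulate: count-level sampling noise
(negative-binomial dispersion), gene–gene correlation, library-size or
GC artifacts, subclonal heterogeneity, and label noise in the
resistance annotation. Tests passing on this generator therefore
demonstrate that the pipeline recovers the signal structure it assumes —
independent Gaussian log-expression with additive batch and class
effects — not that it would perform identically on real tumors.

## Preprocessing

Cohort matrices are merged on the intersection of their gene-ID sets
(sorted lexicographically); union-with-imputation is deliberately not
offered. The low-expression filter keeps genes with TPM ≥ `min_tpm`
(default 1.0) in at least `min_fraction` (default 0.2) of samples pooled
across cohorts; both bounds are inclusive and both knobs are exposed —
the threshold is a common TPM convention, not an estimate. The 2:1
train/test split is stratified by (cohort, class): each stratum
contributes floor(n/3) test samples, at least one when n ≥ 2 so no
evaluation stratum is empty; singleton strata go to training with a
warning. Gene IDs are opaque strings; Ensembl ".N" version stripping is
opt-in to avoid silent collisions.

## Two-tier gene selection

Tier 1 (cross-cohort concordance): per gene and cohort, a two-sided
pooled-variance Student's t-test on log2(TPM+1); the result is the
intersection of the per-cohort sets {p < alpha}, alpha = 0.05. Genes
with zero variance in both classes are skipped with a warning. Welch's
test is available by flag.

Tier 2 (within-cohort robustness): 100 bagging trials; each draws m
samples per class with replacement, m = minority-class size, tests every
gene with a two-sided Mann–Whitney U (exact null when the pooled trial
size is ≤ 12 and tie-free, otherwise normal approximation with tie and
continuity corrections), and counts trials with p < alpha. Genes with
count strictly greater than 80 are selected. "Balanced" resampling is
read as bootstrap (with replacement); subsampling without replacement is
available by flag. No multiple-testing correction is applied at either
tier: the cross-cohort intersection and the trial-frequency filter are
the false-positive guards.

A property worth knowing: bagging trials are resamples of one fixed
dataset and are therefore strongly correlated through it. On pure-noise
data a gene whose *realized* sample difference is extreme (|z| ≳ 3,
about 8 expected among 2000 null genes at n = 30/30) stays significant
in most bootstrap trials and can pass the 80-trial bar. The frequency
filter controls significance *stability under resampling*, not the
family-wise error over genes; on null data it passes roughly 0.5% of
genes — exactly the sample extremes — rather than none. The test suite
pins this behaviour.

Selection always runs on training splits only; using test samples would
leak into the downstream evaluation.

## Deep ensemble

Each member is a fully connected network: `n_hidden_layers` ReLU layers
of `hidden_units` each with inverted dropout, a single sigmoid output,
trained with mini-batch Adam (beta1 = 0.9, beta2 = 0.999) on binary
cross-entropy for a fixed epoch count — epochs are a grid axis, so there
is no early stopping. Weight init is He-normal. Training, batch
shuffling and dropout draw from one generator per member, seeded
deterministically from (ensemble seed, fold, grid index), so a full
retrain reproduces scores to float precision.

The default grid is the Cartesian product
learning rate {0.01, 0.003, 0.001, 0.0003} × layers {1, 2, 3} ×
units {8, 16, 32, 64, 128} × dropout {0, 0.25, 0.5} ×
batch {8, 16, 32} × epochs {25, 50, 100, 200} — 2160 combinations. The
specific axes are this package's realization of a grid of that size;
they are config-overridable (`grid_axes`). Desk-scale runs use
`small_grid()` (12 entries) or `tiny_grid()` (2 entries, used for the
many ensembles of the random-panel null); a seeded `grid_subsample`
option thins any grid.

Inputs are z-scored per gene with the training-fold statistics of each
member (selection and test data are standardized with those same
per-member statistics, never their own). Genes constant across the whole
primary training set are dropped with a warning; a gene constant within
one fold only gets sd clamped to 1, making its z-score constant and
uninformative for that member rather than undefined. Member selection
maximizes ROC AUC on the selection cohort's training data, with ties
broken by lower selection-set cross-entropy, then lower grid index.
Cross-entropy and accuracy are plausible alternative selection metrics;
AUC is the default because the evaluation criterion is rank-based.

The ensemble score is the arithmetic mean of member outputs; the
last-layer embedding is the concatenation of members' final hidden
activations (used for visualizing what the trained ensemble encodes).

## Evaluation

ROC AUC uses the Mann–Whitney formulation (ties count 1/2). Binary
calls use score ≥ threshold with resistant positive. The
sensitivity-prioritized threshold enumerates the observed scores plus
−inf and returns the one maximizing specificity subject to
sensitivity ≥ floor (default 1.0), resolving specificity ties to the
higher threshold; with the ≥ rule a floor ≤ 1 is always attainable.

The random-panel null draws `n_draws` gene panels of the discovered
panel's size uniformly without replacement from the filtered pool
(draws are not forbidden from touching the observed panel's genes),
trains the same fold-wise ensemble on each, and scores the selection
cohort's test split. The empirical p is the add-one estimator
(1 + #{null ≥ observed}) / (1 + n_draws), which never returns zero; its
floor with 10 draws is 1/11.

## Pipeline

`run_pipeline` executes simulate/load → merge+filter+split → select →
train → evaluate (→ null) from one YAML config. A single master seed
derives per-stage seeds by fixed offsets (+1 simulate, +2 split,
+3 select, +4 train, +5 null). The run manifest records the config
hash, stage seeds, package version and SHA-256 digests of every stage
output; deterministic stages reproduce identical digests for identical
configs. Config validation rejects unknown keys with the offending
field path (CLI exit 2); stage failures exit 1.

## Problem sizes used in the shipped analyses

The analysis scripts and the acceptance script use 2000 genes with
5 shared + 5-per-cohort planted genes at effect 2.0, the default cohort
sizes, the 12-entry grid with k = 5 folds, and a 10-draw null with the
2-entry grid — sizes chosen so a complete run finishes in well under a
minute on one CPU while leaving every stage's statistical behaviour
measurable.

## Known limitations

* The Gaussian log-normal generator understates the dispersion and
  correlation structure of real tumors; recovery rates on it are upper
  bounds.
* The bagging frequency filter's false positives are sample extremes
  (see above); on real data the tier-2 lists should be read as
  "robustly differential in this cohort's sample", not as
  error-controlled discoveries.
* With 10 null draws the empirical p cannot go below 0.091;
  distinguishing "better than random panels" at conventional levels
  needs more draws than the desk-scale default.
* Thresholds tuned to a 100% sensitivity floor on small selection
  cohorts are fragile: a single low-scoring resistant sample drags the
  threshold down and specificity with it.
* Training is CPU-bound dense linear algebra; the full 2160-entry grid
  times 5 folds is a cluster-scale search and is not run by default
  anywhere in the repository.
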