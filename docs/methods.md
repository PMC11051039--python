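# Methods

## Overview

`ifselect` implements an explainable classification pipeline for labeled
expression matrices: importance-based gene ranking, incremental feature
selection (IFS) over nested top-k prefixes with class-balanced
cross-validated evaluation, essential-subset extraction with cross-list
consensus, and decision-tree rule derivation. The pipeline is
classifier-agnostic in principle; this package pins decision trees (DT) and
random forests (RF) as the evaluation classifiers because they are the
standard pairing for rule-oriented analyses.

## Synthetic data model

The generator emulates a log-normalized scRNA-seq matrix labeled with one
of three smoking statuses (active / former / never), the setting the
pipeline is designed for:

* Every entry is `max(0, N(mu, sigma))` with `mu = baseline_mean` plus, for
  planted marker genes, a class-dependent shift; entries are then zeroed
  independently with probability `dropout_rate` (Bernoulli dropout).
  A Gaussian on the log-normalized scale keeps every downstream check
  analytically tractable (Welch t, binomial dropout fraction,
  class-conditional mean recovery at `3·sigma/sqrt(n)`).
* Class compositions come from presets mirroring the four lung cell
  compartments (endothelial 6521/7189/29829, epithelial
  37905/47945/148499, immune 41801/34853/113189, stromal
  3415/2342/10274 active/former/never cells), rescaled by
  largest-remainder rounding so scaled totals are exact.
* Defaults: 1,500 cells, 2,000 genes, 15 planted markers shifted by
  3 noise SDs in one class each (five markers per class, which separates
  every pair of classes), `baseline_mean = 1.0`, `noise_sd = 0.5`,
  `dropout_rate = 0.3`. These are desk-scale stand-ins for atlas-sized
  inputs (hundreds of thousands of cells, ~28k genes); a full-scale matrix
  is not a reasonable test fixture, and every structural property being
  tested is size-independent.
* Gene identifiers are zero-padded ENSG-like strings so the id→symbol
  mapping path is exercised.

The generator deliberately does **not** model UMI count distributions,
gene–gene correlation, batch effects, or cell-type hierarchies. Passing
recovery tests therefore demonstrates that the pipeline finds planted
mean-shift signal under imbalance, dropout and noise — not that it
overcomes correlated confounders in real atlas data.

## Feature ranking

Eight criteria are exposed under one interface; all rank on the full
dataset (ranking happens once, upstream of the evaluation loop):

* **AdaBoost, ExtraTrees, RF** — scikit-learn ensembles, impurity-decrease
  importances, pinned at 100 estimators.
* **XGBoost, LightGBM** — gain importances, 100 trees, single-threaded and
  deterministic-mode so rankings are reproducible.
* **CatBoost** — optional; enabled only when the `catboost` package is
  importable, and excluded from the default ranker set otherwise.
* **LASSO** — one-vs-rest L1-penalized logistic models; the importance of
  a gene is the maximum |coefficient| across class models. The
  regularization strength is chosen from a small grid
  (C ∈ {0.01, 0.1, 1}) by 3-fold cross-validated accuracy; ties prefer the
  strongest penalty. A linear one-vs-rest formulation keeps "coefficient
  magnitude = importance" well-defined for more than two classes.
* **MCFS** — implemented from scratch (see README formula): s random
  feature subsets × t stratified train/test splits, one entropy-criterion
  tree each; a gene's score accumulates
  `wAcc^u · IG(node) · coverage_ratio^v` over nodes splitting on it.
  Defaults: `s=100`, `m = ceil(0.1·n_genes)` capped at 500, `t=5`,
  `train_fraction=0.66`, `u=v=1`. The exponent and sampling defaults are a
  package decision (the original MCFS literature leaves them
  tool-configurable); they keep desk-scale runtime in minutes and are
  exposed for sensitivity analysis. With `u=v=0` the score provably
  reduces to summed information gain, which the test suite exploits as an
  oracle.

Ties in every ranking are broken by ascending gene id, so rankings are
total orders and reproducible. Hyperparameters are pinned explicitly
rather than inherited from library defaults, so rankings do not drift
across library upgrades.

## Class balancing

SMOTE is implemented in-package: each non-majority class is upsampled to
the majority count by `x + r·(z − x)` with `z` one of the k (default 5)
Euclidean nearest same-class neighbors and `r ~ U(0,1)`. `k` is clamped to
minority-size − 1 with a logged warning; a singleton class is an error.
Balancing is applied **inside each training fold only** — never to
evaluation folds — so synthetic samples can never leak into test data.
Whether balancing belongs inside or outside cross-validation is a genuine
methodological fork; the fold-internal choice is the leakage-safe one and
is recorded here as a deliberate decision.

## Incremental feature selection

Prefix sizes are `step, 2·step, …` up to `top_n` (default 5 … 200; `top_n`
appended when not a multiple). Each prefix is evaluated with stratified
k-fold cross-validation (default 10 folds). Stratification is required
under strong imbalance (plain folds can lose a class entirely); held-out
predictions are pooled across folds before computing metrics, giving one
confusion table per curve point and robustness to small folds. Classifier
defaults are pinned: DT = CART with Gini, unlimited depth; RF = 100 trees,
√d features per split.

## Metrics

* `weighted_f1` is the harmonic mean of class-share-weighted precision and
  class-share-weighted recall. This differs from the more common weighted
  average of per-class F1, which is provided as `weighted_f1_classic`; the
  harmonic-mean form is the default everywhere the pipeline says
  "weighted F1".
* Per-class precision with an empty prediction column (TP+FP = 0) is
  defined as 0 (logged), keeping the weighted sums finite; when both
  weighted precision and recall are 0 the score is 0.
* Multiclass MCC follows Gorodkin's R_K construction: the correlation of
  the n×L one-hot indicator matrices of true and predicted labels, with
  covariance summed over indicator columns. It equals the classical binary
  MCC for L = 2 (verified exhaustively over small tables) and returns 0
  with a logged note when an indicator matrix is constant.

## Essential subsets and consensus

The maximum point of a curve is the smallest k attaining the maximal
weighted F1 (parsimony tie-break). When the maximum needs at least
`k_threshold` features (default 100), the smallest earlier k scoring
within `delta` (default 0.015) of the maximum replaces it as the
"relatively high" point; 0.015 reflects a one-point-of-F1-per-hundred
trade against a halved gene panel and both knobs are config-exposed.
Essential subsets default to the RF curves (RF dominates DT throughout the
sweep). Consensus counts per-gene selection frequency across lists and
tabulates exact list-combination cells (upset-diagram form); cells
partition the union of selected genes.

## Rule extraction

One CART tree is fit on the SMOTE-balanced full dataset restricted to an
essential subset (a single final refit gives one canonical rule set, as
opposed to per-fold trees). Every root-to-leaf path becomes a rule;
same-gene same-side bounds are merged to the tightest threshold, which is
an equivalence transformation (verified pointwise in tests). The rule set
is mutually exclusive and exhaustive and reproduces the tree's predictions
exactly; leaf class assignment uses the tree's own value argmax so
tie-breaks match the fitted model. Tree depth is unlimited by default
(`--max-depth` trades rule count for readability).

## Determinism

A single seed drives everything. Stage seeds are derived by CRC32-hashing
the parent seed with string tokens naming the consumer
(`derive_seed(seed, "smote", fold)`), so adding a stage never perturbs
another stage's stream, and all derived seeds stay below 2³¹. JSON output
is key-sorted with fixed float handling; repeated runs are byte-identical
(asserted in tests at 300 cells × 400 genes across the whole CLI chain —
determinism is size-independent, so the check does not need the large
fixture).

## Problem sizes used in validation

Structural and metric tests run on 150–300-cell fixtures. Parameter
recovery runs on the default 1,500 × 2,000 fixture with all enabled
rankers (MCFS at s=100): every ranker places ≥80 % of planted markers in
its top 30, RF-based IFS exceeds weighted F1 0.95 within 50 features, and
rule predicates reference planted markers almost exclusively. These sizes
keep the full suite in minutes on one CPU.

## Known limitations

* The Gaussian/dropout generator is a deliberately simple null model; see
  above for what it does not emulate.
* LASSO grid search covers three penalty values; pathological scalings may
  want a wider grid.
* `weighted_f1` (harmonic-mean form) is not decomposable into per-class
  F1; per-class reporting uses the standard per-class F1 values.
* Consensus treats subsets as sets; within-subset rank order is not
  weighted.
* No early stopping in the IFS sweep: the full grid is always evaluated.
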