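# Methods

This note documents the models and procedures implemented in
`panelomics`, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
conventions the tests rely on.

## Data model and preprocessing

An `OmicsTable` is a samples × features matrix with NaN for missing
cells and a namespace prefix on every feature id encoding its omics
layer (`prot:`, `gly:`, `met:`). Merging layers concatenates columns in
the canonical order proteomics, glycomics, metabolomics after aligning
sample order to the first table. A missingness ceiling of 1% is
enforced at load time, matching the sub-1% missingness typical of
curated targeted MS panels.

Preprocessing is deliberately minimal: per-feature median imputation
followed by z-scoring with the *sample* standard deviation (ddof = 1).
Both statistics always come from a caller-designated fit subset of
samples, so cross-validated evaluation can guarantee that held-out rows
are transformed with training-fold statistics only. A feature with zero
variance on the fit rows is standardized to zero and reported in a
warning record rather than producing infinities. Intensities are used
as-is by default; an optional log2 transform is available at the
configuration level by generating or supplying log-scale tables
(`SyntheticSpec.log_scale`), since rank-based quantities (single-feature
AUC) and the t-test under the null are unaffected by monotone
transforms.

## Univariate statistics

* **Student t** — classical pooled-variance two-sided test (not Welch),
  cases minus controls, df = n₁ + n₂ − 2. Missing values are dropped
  per feature. Zero pooled variance is handled degenerately: p = 1 when
  the means agree, p = 0 otherwise, with a flag.
* **Single-feature AUC** — Mann–Whitney U/(n₁n₂) with ties counted ½.
  Orientation is kept raw: AUC < 0.5 means the feature is lower in
  cases; the direction is recoverable from the value itself.
* **Screening counts** — number of features per layer with raw p ≤ α
  (default 0.05). No multiplicity correction is applied at this stage;
  the counts describe a screen, not an inference.
* **Top-K per omics** — ascending p, ties broken by |t| descending then
  feature id, so rankings are reproducible byte-for-byte.
* **Fisher exact (2×2)** — two-sided p by the point-probability rule:
  the sum of hypergeometric probabilities, over all tables with the
  observed margins, that do not exceed the observed table's
  probability. Computed in exact integer arithmetic (binomial
  coefficients), so no floating-point tie tolerance is needed; tests
  cross-check against an independent enumeration and against
  `scipy.stats.fisher_exact`.

## Feature rankers

All rankers consume the standardized combined matrix and emit a
`FeatureRanking`: a total order over features, a non-increasing score
vector, and the selected top-n panel. For elimination-based methods the
reported score is the elimination rank (higher = survived longer); the
native statistic (squared SVM weight, Shapley score at elimination) is
kept in `raw_scores`. Ties anywhere are broken lexicographically by
feature id.

* **SelectKBest** (`select_kbest_rank`) — one-way ANOVA F via
  scikit-learn's `f_classif`. For two groups F = t² with the pooled t,
  so this ordering coincides with ascending-p univariate screening.
  Constant features receive F = 0 and rank last.
* **Elastic net** (`elastic_net_rank`) — scikit-learn `ElasticNet` on
  the regression objective with 0/1 labels, l1_ratio fixed at 0.5.
  When no α is given it is chosen by internal 5-fold CV over a fixed
  grid of 40 log-spaced values in [1e-4, 1] (deterministic, unshuffled
  folds), followed by a tight refit (tol 1e-8) at the chosen α. Zero
  coefficients are appended after all nonzero ones in input order; an
  all-zero fit degenerates to input order with a warning.
* **SVM-RFE** (`svm_rfe_rank`) — libsvm linear SVC (C = 1), importance
  wⱼ², eliminating `step` (default 1) lowest-weight features per
  retrain until `n_select` remain.
* **Random forest** (`rf_rank`) — 500 trees, √p features per split,
  seeded. Two importance modes: `impurity` (mean decrease in impurity,
  scikit-learn's native score) and `shap` (default): per-sample
  root-to-leaf path attribution, crediting each split's change in the
  node class-1 fraction to the split feature and averaging over trees.
  Path attributions are exactly additive — per sample they sum to the
  forest's predicted probability minus the base rate — which the tests
  assert to 1e-6. Their null distribution across features is heavier-
  tailed than impurity importance, so flatness-on-noise checks use the
  impurity mode.

## Transformer-RFE

The estimator is a small cross-attention classifier built for tabular
n ≪ p data:

* each feature j of sample i becomes a token
  `x_ij · v + E_feat[j] + E_layer[layer(j)]` in `d_model` dimensions;
* a single learned query vector cross-attends over all feature tokens
  through `n_attention_layers` pre-norm blocks (multi-head attention
  with the query as the only attending position, then a 2× feed-forward
  layer, both with residual connections);
* the final query representation feeds a linear binary head.

Because only the query attends, compute per forward pass is O(n·p·d²)
and parameters are O(p·d), trainable at n = 89. Defaults: d_model 16,
4 heads, 2 blocks, dropout 0 (regularization comes from early
stopping), full-batch Adam at learning rate 1e-2, at most 150 epochs
with early stopping (patience 20, not before epoch 40) on the binary
cross-entropy of a 20% stratified validation split; the
best-validation parameters are restored. `val_fraction=0` trains on
everything to convergence (used for capacity checks). Everything is
reproducible from the config seed; validation splits, dropout and
Shapley permutations use seeds derived from it via `SeedSequence`.

**Importance** is a model-agnostic permutation-Shapley estimate: for
each evaluation sample, features are revealed one at a time in random
orders starting from the background vector (the training-set feature
means), and a feature's attribution is its average marginal change in
the model logit. The per-feature score is the mean |attribution| over
samples. The estimator satisfies the efficiency axiom exactly for every
permutation (telescoping), which the tests assert at 1e-9, and the
null-player axiom exactly. Defaults: 128 permutations standalone;
16 permutations inside the RFE loop, where only the identity of the
minimum matters and scores are re-estimated after every retrain.
Feature tokens are static across blocks, so the key/value projections
are cached and masking one feature updates one token row — this makes
the sweep incremental rather than a full forward pass per step.

**Elimination** removes exactly one lowest-scoring feature per
iteration (ties lexicographic), retrains from a fresh derived seed
(no warm start), and keeps the eliminated feature's score frozen at
elimination time. The ranking lists survivors by final-model scores
followed by eliminated features in reverse order; the full trace
(surviving set, eliminated feature, score, iteration seed) is returned
for audit. `estimator_factory` lets any model with a
`decision_function` and a `background` replace the transformer — the
test suite uses a linear-SVM stub to show the Shapley-driven loop
reproduces classical SVM-RFE elimination on a balanced-sign design.

## Graph fusion (per-view GCN + label-space fusion)

A compact multi-view classifier in the style of graph-convolution
multi-omics integrators: per layer, a sample-similarity network from
cosine similarity with top-k (default 10) neighbor sparsification,
symmetrized by elementwise max, self-loops added, symmetric degree
normalization; a 2-layer GCN per view produces per-sample class
probabilities; the flattened outer product of the per-view probability
vectors (2^V entries — the label-space cross-view correlation tensor)
feeds a small dense head (hidden 16) for the final probabilities.
Training is transductive (all samples in the graph, loss on the
training mask only), full-batch Adam, 300 epochs, loss = fusion
cross-entropy plus per-view cross-entropies. kNN sparsification rather
than a similarity threshold guarantees every sample keeps neighbors at
n = 89. This is a minimal reimplementation from a three-sentence
description of the original architecture, not a port; it exists so the
benchmark harness covers a graph-based integrator.

Post-hoc importance is single-feature ablation: replace a feature
column by its training-mask mean (rebuilding that layer's similarity
network), measure the increase in training-mask loss, clamp at zero.
Per-sample Shapley values are ill-defined for a transductive graph
model — masking a feature changes every sample's embedding through the
graph — so ablation is the closest well-defined analog.

## Panel evaluation and benchmark

A panel is evaluated with L2 logistic regression (C = 1, threshold 0.5)
under stratified 5-fold CV, imputation and standardization refit inside
every training fold. Accuracy and AUC are averaged across folds (the
mean ± sd reporting convention); pooled out-of-fold probabilities are
kept only for the ROC curve. Fold assignment is seeded and exported.

The benchmark's default protocol mirrors the common study design:
each method selects its panel on the *full* table, then the panel is
cross-validated. This select-then-evaluate protocol is optimistic —
on null data its AUC exceeds the leakage-safe alternative in
expectation, which a dedicated test demonstrates — so a
`leakage_safe=True` mode re-runs selection inside every training fold
and reports held-out performance of fold-specific panels.

Consensus is a count rule: features appearing in ≥ 2 methods' top-n
lists. Applied to the seven published top-5 panels this yields exactly
the six multiply-selected features, one of the two analytically fixed
worked examples (the other: Fisher p = 0.2492 for 0/40 vs 3/49).

## Synthetic cohorts

`generate_cohort` draws log-scale feature values from a multivariate
Gaussian with unit variance and exchangeable correlation `block_rho`
(default 0.3) inside consecutive blocks of `block_size` (default 10)
features, independent across blocks and layers. Informative features
get a location shift of `d` standard deviations in cases on the log
scale (fold-change semantics); values are exponentiated around
per-feature baseline log-intensities N(10, 1.5²) unless `log_scale`
keeps them Gaussian. Missing cells are masked completely at random
(default rate 0.005). Defaults mirror the study design the package
targets: 40 cases vs 49 controls, layers of 100/82/60 features,
24 planted effects at d = 1.

The location-shift construction gives the closed form
AUC = Φ(d/√2) for a single informative feature, which calibration
tests exploit (d = 1 → 0.760, d = 2 → 0.921). What the generator does
**not** emulate: batch effects and drift, cross-layer correlation
(configurable in principle, default absent, realism untested),
intensity-dependent missingness, heavy-tailed or multiplicative noise
beyond log-normality, and biological pathway structure. Passing
recovery tests therefore demonstrate correctness of the algorithms
under a known generative model, not expected performance on real
cohorts.

## Problem sizes used by tests and the acceptance script

Simulation sizes were fixed once as a compromise between statistical
resolution and a single-CPU run:

* t-test calibration: 200 null cohorts of 89 × 100 (20 000 pooled
  tests).
* Leakage-safe null benchmark: classical rankers at 89 × 100 over 10
  seeds; transformer-RFE and graph fusion at 89 × 30 over 3 seeds
  (their null behavior does not depend on extra noise columns, and a
  full-width sweep would be orders of magnitude slower). A single
  replicate's null AUC has sd ≈ 0.09, so the [0.3, 0.7] calibration
  band is asserted on each method's mean over seeds (sd ≈ 0.03), with
  a 3σ-level [0.2, 0.8] sanity bound per replicate.
* Recovery: classical rankers — one planted d = 3 feature among 50,
  20 seeds, ≥ 95% top-5 retention; transformer-RFE — three planted
  d = 2 features among 30 at n = 89, 20 seeds, ≥ 2/3 recovered in
  ≥ 80% of seeds.
* Closed-form limit: one d = 1 feature at n = 5000, CV AUC within
  0.02 of Φ(1/√2).
* Determinism: the full six-method pipeline run twice on a 40 × 24
  cohort, outputs compared byte-for-byte.

## Known limitations

* The transformer and GCN train on an in-package numpy autodiff
  engine: single-threaded, full-batch only. A 242 → 5 transformer-RFE
  sweep takes hours on one CPU; the method is practical at panel-scale
  feature counts (≤ ~100) or after a univariate pre-screen.
* Elastic-net coordinate descent resolves near-zero coefficients in
  iteration order; orderings among |coef| < 1e-6 are numerical ties.
* Variable-importance-in-projection (VIP) ranking is not implemented;
  tree-path/Shapley and impurity importances are the supported post-hoc
  modes.
* Binary phenotypes only; no multi-class support, no covariate
  adjustment, no external-validation-cohort handling.
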