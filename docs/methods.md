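# Methods

## Model

`cellstack` treats cell-type annotation as supervised multi-class
classification of an n × m non-negative expression matrix (n cells, m genes,
t cell types) and builds a two-layer stacked ensemble whose architecture is
*dynamic*: the number of first-layer models (t·L) and the meta-feature width
(t·L·t) grow with the number of types in the training labels.

**Normalization.** Each cell is scaled to a fixed total (`target_scale`,
default 1e4 — counts-per-ten-thousand, the conventional single-cell target)
and log1p-transformed by default. Normalization is strictly per-cell, so it
commutes with any permutation or subsetting of cells, and it is applied to
training and test data independently: no statistic crosses the split.
All-zero cells are a data-quality signal and raise an error by default; an
explicit flag drops them with a warning instead.

**χ² signatures.** For each type, labels are binarized one-vs-rest and genes
ranked by the frequency-based χ² statistic over class-wise expression sums
(the formulation used by standard feature-selection implementations):
χ²_j = Σ_c (O_c − E_c)²/E_c with E_c = T_j·N_c/n. Genes with zero total
score 0 by convention. Scores are computed on the *normalized* values — the
same representation the classifiers see — which remain non-negative under
log1p, so the χ² precondition holds. Top-k ties are broken by lexicographic
gene ID so that rankings are reproducible across platforms; k defaults to
300 per type and signatures are allowed to overlap across types.

**First layer.** For each (signature, learner) pair the signature-restricted
sub-dataset is split into 3 stratified folds (stratification guarantees every
type appears in every training split; a class smaller than the fold count is
a hard error with remediation hints, never a silent fold reduction). The
learner trains on the complement of each fold and predicts t class
probabilities for the held-out cells, so each cell's feature block comes from
a model that never saw it. The blocks are concatenated — outer loop over
types in lexicographic codebook order, inner loop over learners in declared
order, innermost the t class probabilities in codebook order — giving the
n × (t·L·t) meta-feature matrix. After the out-of-fold pass each base learner
is refit on its full sub-dataset; these refit models perform the test-time
transform. Default learners: RBF-kernel SVM (C = 1, kernel scale 1/(m·var),
Platt-calibrated probabilities, seeded) and L2 logistic regression (C = 1).
Random forest, gradient boosting and a multilayer perceptron are available
as alternatives; any learner must emit a valid probability vector.

**Second layer.** A multinomial L2 logistic regression (C = 1) over the
meta-feature columns. Predicted type = argmax of its probabilities, ties
resolved by codebook order. A query cell whose true type is absent from the
reference is necessarily assigned some training type — the model has no
rejection option.

## Evaluation protocols

* **intra** — stratified k-fold CV (default 5) within one dataset; metrics
  averaged over folds, per-fold reports retained.
* **inter / cross-batch / cross-species** — fit on training data only,
  evaluate on an independently normalized test set. Multiple training sets
  are pooled over the *intersection* of their gene spaces (a union would
  require imputing values inside training data). At predict time the test
  matrix is projected onto the signature gene space; genes missing from the
  test data are zero-filled with a warning.
* **repeated down-sampling** — every class larger than a per-class target is
  randomly reduced to exactly the target (smaller classes kept whole, cell
  order preserved); the down-sample → fit → evaluate round is repeated
  (default 5×) and metrics are arithmetic means. Round r draws its sample
  with seed ``seed + r`` while the fit keeps the base seed, so rounds differ
  only through the sampled cells and the protocol is reproducible from one
  seed (with a degenerate target the rounds are identical).

Metrics: accuracy; per-class F1 = 2PR/(P+R) with the 0-when-undefined
convention, computed over the classes present in the *test truth* (a class
that appears only in predictions contributes a confusion-matrix column but no
F1 term — the convention that stays well-defined under cross-species label
mismatch); macro F1 = unweighted mean; median F1 = median (midpoint of the
two central values for an even class count).

## Synthetic data

The generator draws counts from a negative binomial via a gamma–Poisson
mixture with mean μ and variance μ + φμ² (φ = `dispersion`). Each type owns
`markers_per_type` disjoint marker genes whose mean is multiplied by
exp(`log_fold_change`) in that type's cells. Batch effects, when enabled, are
per-batch per-gene multiplicative log-normal factors (sd `batch_effect_sd`),
the simplest structure that makes cross-batch evaluation non-trivial.

Defaults describe a deliberately well-separated population: 3 types × 200
cells, 2000 genes, 20 markers per type, log-fold-change 2 (≈7.4× up-shift)
over base mean 5, φ = 0.3, one batch. These sizes keep every test and the
acceptance script within a few minutes on one CPU while leaving enough cells
per class for stratified 5-fold CV over 3-fold stacking.

What the generator does **not** emulate: zero inflation and protocol-specific
dropout, realistic library-size variation, correlated gene modules,
continuous differentiation trajectories, or ambient contamination. Passing
tests therefore demonstrate that the machinery is correct (selection recovers
planted signal, stacking is leakage-free, protocols are reproducible), not
that any particular accuracy will transfer to real tissues.

## Numerical and design choices

* χ² is linear under per-gene positive scaling and is compared with an
  independent brute-force oracle at 1e-9 relative tolerance in tests.
* Probability blocks must sum to 1 within 1e-6; learner outputs are mapped
  onto the codebook column order explicitly, so a fold that happens to miss
  a class (impossible under the size checks, but defended anyway) cannot
  scramble columns.
* All randomness — simulation, fold assignment, SVM calibration, sampling —
  flows from explicit integer seeds; two fits with the same seed and input
  are bit-identical, and a saved model predicts identically after reload.
* Gene/cell ID collisions raise errors rather than de-duplicating: silent
  merging would corrupt signatures.
* Model files are format-versioned; corruption and version mismatch are
  distinct, named errors.

## Limitations

No rejection of novel cell types; no batch-effect *correction* (only
evaluation across batches); no doublet or QC filtering; the χ² selector
assumes non-negative features and is blind to down-regulated markers under
log1p values near zero.
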