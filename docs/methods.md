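# Methods

## Model and pipeline

`hormobind` treats hormone-binding protein prediction as binary sequence
classification. The pipeline has four stages, each an importable module:

1. **Encoding** (`hormobind.encoders`) — a sequence (or its PSSM) becomes a
   fixed-length real vector.
2. **Selection** (`hormobind.selection`) — features are ranked by the
   one-way ANOVA F statistic and the top *m* kept.
3. **Classification** (`hormobind.nb`) — Gaussian naive Bayes.
4. **Evaluation** (`hormobind.evaluation`) — stratified K-fold
   cross-validation with confusion-matrix metrics and ROC/PRC curves.

## Encoders

**k-mer.** Entry `w` is `count(w) / (L − k + 1)` over the overlapping
windows. Frequencies rather than raw counts are used so that the vector is
a probability distribution and sequence length drops out; the denominator
is the number of overlapping windows, the standard convention. `k` is
capped at 3 by default (20⁴ = 160 000 dimensions invites overfitting on
datasets of a few hundred sequences); an explicit override flag lifts the
cap.

**DR.** The distance-0 block holds the 20 single-residue counts; each
distance-d block (d = 1..dMAX) holds the 400 ordered-pair counts of
`(R_i, R_{i+d})`. Raw counts are kept (no normalization) — the block sums
`L`, `L−1`, …, `L−dMAX` are themselves tested invariants. Default
dMAX = 3, a moderate horizon: local pair statistics beyond a few positions
add dimensions much faster than signal at these dataset sizes.

**CC-PSSM.** Column means are taken over all L positions (the "average
score along the protein sequence"), not over the L − lag summed terms. The
380 ordered pairs of distinct residues are emitted lag-major, pairs in
row-major (i1, i2) order; the order is fixed and recorded in the feature
names (`cc:lag1:A-C`). PSSM scores are used exactly as read — no sigmoid
or z-score rescaling. Default LAG = 2. Note 380 × 2 = 760 dimensions; the
dimension is always computed from the formula, never hard-coded.

All encoders are per-sequence maps: permuting the dataset permutes the
feature-matrix rows identically, so encoding before splitting into CV
folds leaks nothing.

## F-score selection

The score is the classical one-way ANOVA F statistic

    F(i) = [ssb(i)/(K−1)] / [ssw(i)/(N−K)]

in its multi-class form (K = number of classes), although the shipped
pipeline is binary. Two degenerate cases get explicit values: `ssw = 0`
with `ssb > 0` is a perfect separator and scores `+inf` (dropping it would
discard the strongest feature); a globally constant feature scores 0, not
NaN. Ties rank by ascending feature index so the order is a deterministic
permutation. Default m = 250, configurable.

By default selection is re-fit inside each CV training fold, so the test
fold never influences which features are kept. The `--pre-cv-selection`
mode instead selects once on the full dataset before splitting — a
protocol that still appears in the applied literature but is optimistically
biased, since test samples contribute to the ranking. Both are provided;
results on real data will differ between them, and the within-fold number
is the honest one.

## Gaussian naive Bayes

The class posterior factorizes as `P(y|x) ∝ P(y) Π_i P(x_i|y)`. The
per-feature likelihood is a univariate Gaussian — the natural choice for
continuous frequency/covariance features (a multinomial variant would
require discretization and is out of scope). Parameters:

- priors = class frequencies (no prior smoothing; intended for
  near-balanced designs);
- per-class maximum-likelihood moments (variance divided by the class
  count, consistent with the probabilistic model — at class sizes around
  100 the difference from the unbiased estimator is immaterial);
- variance floor `max(smoothing · max_f Var(x_f), 1e−12)` with
  smoothing = 1e−9 by default. Selected k-mer features are sparse, so a
  feature being constant within one class is common; the floor keeps the
  density proper. Classes need ≥ 2 samples for a variance to exist.

All likelihood sums run in log space and the posterior is a softmax over
per-class log scores, so 8000-dimensional inputs cannot underflow and the
division by P(x) is implicit in the normalization. Exact posterior ties
resolve to the earliest entry of `class_labels` (sorted label order).
Models serialize to JSON with full float precision; a round-trip
reproduces predictions bit-for-bit on the same platform.

## Evaluation

Metrics follow the standard confusion-matrix formulas (SN, SP, ACC,
precision, F1, MCC). MCC, precision and F1 are defined as 0 when a
denominator factor vanishes — the usual convention, which keeps degenerate
folds finite instead of crashing.

ROC is swept over distinct score thresholds in descending order, anchored
at (0,0) and (1,1); AUROC is trapezoidal, which equals the Mann–Whitney
concordance probability with ties counted ½ (a tested identity). AUPRC
uses the step-wise rule `Σ (R_t − R_{t−1}) P_t`; linear interpolation of
precision is deliberately avoided because it overstates the area.

Cross-validation is stratified: each class is shuffled with a seeded
generator and dealt round-robin into K folds, so fold class balance is
within one sample of the dataset's and single-class folds cannot occur
when both classes have ≥ K members. The headline numbers pool confusion
counts over folds; per-fold mean ± sd are also reported because averaging
per-fold metrics is the other common aggregation and the two can differ.
Default K = 10, seed = 42; the fold assignment and seed are stored in
every report, making any run exactly reproducible.

## Synthetic data

The generator emulates what the pipeline's features actually measure:
class-dependent residue composition. Each class draws residues i.i.d. from

    p_class(δ) = (1 − δ) · uniform + δ · enriched_class

where the enriched profiles put 0.15 on four class-specific residues
(positive: A, K, L, S; negative: D, G, P, V — disjoint sets of common
residues, chosen once) and spread the rest uniformly. δ = 0 gives
identically distributed classes (any classifier must sit at chance);
δ = 1 the maximal divergence. An optional first-order Markov transition
matrix supports correlated compositions. Synthetic PSSMs add a signal σ at
the true residue's column on top of unit Gaussian noise per cell.

The frozen reference benchmark is 100 + 100 sequences, lengths uniform on
[80, 300], δ = 0.6, seed 42 — sized like a typical curated protein
benchmark of a few hundred sequences and comfortably separable by
composition features. Every generator output is a pure function of
(spec, seed): one named `numpy` generator per call, no global state.

What the generator does *not* emulate: homology structure and redundancy
(real benchmarks need CD-HIT-style filtering first — this package does
not cluster), motif- or domain-level signal, realistic length/composition
coupling, and UniProt annotation noise. Passing the synthetic benchmark
therefore demonstrates that the pipeline's machinery is correct and
well-calibrated, not that any particular accuracy will be reached on real
hormone-binding proteins; accuracy on real data depends on the dataset and
on the selection protocol chosen.

## Numerical and design notes

- FASTA records are upper-cased and a single terminal `*` stripped before
  validation; any other non-alphabet character triggers the policy
  (default `strict`). There is no masking mode — sequences with unknown
  residues (`X`, `Z`, `B`, …) are rejected or dropped, never recoded.
- PSSM columns are re-ordered to the canonical alphabet on read, so files
  with any column order (PSI-BLAST's included) yield identical matrices.
  Only the first log-odds block of PSI-BLAST ASCII output is parsed;
  generating real PSSMs is outside the package's scope.
- The k-mer encoder uses a rolling base-20 index; it is property-tested
  against a naive window-scan oracle.
- CC-PSSM is exactly invariant to adding a constant to any column
  (mean-centering); the test asserts this to 1e−8 in floats.
- `k` less than 4 keeps the k-mer dimension at or below 8000; the CLI
  defaults (k = 3, m = 250, K = 10, seed = 42) match the package's
  reference configuration.

## Limitations

- Binary classification only; the F-score and CV machinery accept more
  classes but the CLI and dataset model are two-class.
- No wrapper/embedded feature selection (incremental feature curves,
  mRMR); a single fixed m is the supported protocol.
- Baseline classifiers (random forests, LDA, logistic regression) are not
  re-implemented; any object with `fit` / `predict_proba` / `predict` and
  `class_labels` plugs into `kfold_cv` via `classifier_factory`.
- No calibration of posterior probabilities; Gaussian-NB posteriors are
  typically overconfident at high dimension.
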