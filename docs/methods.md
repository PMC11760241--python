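# Methods

This note documents the statistical and numerical choices behind omixnet:
what each stage computes, the defaults and why, what the synthetic
benchmark does and does not emulate, and the known limitations.

## Encodings

**Per-sample z-scoring.** Expression-like layers (gene, miRNA and protein
expression, DNA methylation) are normalized within each *sample*:
x ↦ (x − μ_s)/σ_s using that sample's mean and population standard
deviation (divisor n) over its observed entries. Per-sample normalization
removes sample-level scale effects (library size, array intensity) and is
applied as the pipeline's canonical direction; per-feature normalization is
available via `zscore_per_sample(..., axis="feature")` for workflows that
prefer it. Population rather than sample sd is immaterial at genome scale
but is fixed for reproducibility. Zero-variance rows map to all-zero
z-scores, avoiding a division by zero and consistent with the missing-value
convention below.

**Missing values.** Missing expression entries are excluded from the mean/sd
computation and then set to 0 *after* normalization — i.e. imputed at the
per-sample mean on the normalized scale. Imputing before normalization
would drag μ_s and σ_s toward the imputed constant; the chosen order keeps
the observed-entry statistics clean. SNP and CNV layers receive no
imputation: a missing genotype is its own one-hot channel, and copy-number
tables must be complete.

**One-hot channel orders.** SNP: (A, T, C, G, missing). CNV: (homozygous
deletion, single-copy deletion, diploid normal, low-level amplification,
high-level amplification), with integer aliases −2…2 accepted on input.
The orders are fixed by declaration and serialized with every trained model
so inference always matches training.

**CpG filtering.** Methylation features can be restricted to CpGs present in
a marker annotation (promoter/gene CpGs); the drop count is reported and an
empty result is an error, since it indicates an annotation/namespace
mismatch rather than a legitimate empty study.

## The multi-branch CNN

One branch per omics layer; 1–3 layers. Branch: for each configured conv
stage (default two: 16 then 32 filters, kernel 4), a 1-D convolution along
the feature axis (encoding channels = input channels, valid padding,
stride 1), leaky-ReLU (slope 0.01), and non-overlapping max pooling of
width 2; then a flatten and a dense projection to a 32-unit representation,
leaky-ReLU, and batch normalization closing the branch. Representations are
concatenated and passed to fully connected layers (64, 16 by default), each
followed by leaky-ReLU and dropout (0.25); the output head is softmax over
classes or one linear unit. Loss is (class-weighted) cross-entropy or mean
squared error; the optimizer is Adam (lr 1e-3, batch 32) with early
stopping on validation loss (patience 10) restoring the best parameters.
Class weights are inverse class frequencies — survival cohorts are often
heavily imbalanced, and unweighted cross-entropy would reward collapsing to
the majority class.

A design point worth making explicit: the branches end in a flatten +
position-specific dense projection, *not* a global pooling of the conv
maps. Convolution weights are shared across positions, so after a global
pool the network retains no information about *which* feature produced an
activation — it can only detect that some window somewhere was extreme.
For tabular omics vectors, where identity of the feature is the signal,
that destroys both classification accuracy and the usefulness of input
gradients: in development the globally pooled variant plateaued near AUC
0.80 on a benchmark where logistic regression reaches 1.0, with essentially
random saliency. Local pooling plus a dense projection keeps translation
sensitivity, and the planted-signal benchmark is recovered (AUC ≥ 0.95,
top-10 saliency dominated by planted markers).

All parameters above are defaults of `ModelSpec`, fully overridable per
run; the published architectures this package's defaults stand in for are
not public, so the defaults are the package's own, chosen to train in
seconds on cohort sizes of a few hundred samples.

Implementation: the forward/backward passes (conv1d, batch norm, dropout,
leaky-ReLU, max pool, dense, softmax/CE, MSE, Adam) are implemented in
numpy inside the package. Backpropagation runs through to the inputs, so
the saliency maps below use exactly the machinery that trains the model;
gradients are finite-difference-checked in the test suite. Batch
normalization uses batch statistics in training and exponential running
statistics (momentum 0.9) at inference. With a fixed seed, weight
initialization, batch shuffling and dropout masks are fully reproducible.

Serialization is a single zip archive: a JSON manifest (format version,
architecture spec, per-layer feature IDs and channel orders, training
history, class labels) plus an `.npz` parameter blob. Load/save round trips
change predictions by < 1e-6 (bit-identical in practice).

## Splits, folds and evaluation

Train/validation/test splits are 60/20/20 by default with *exact* integer
sizes from largest-remainder rounding, stratified by class for categorical
tasks (quantitative tasks split at random). Stratified k-fold
cross-validation (default k = 5) partitions all samples with fold sizes
within one; during CV the model refits per fold, carving a stratified 20%
of the training part for early stopping. Both plans serialize to JSON and
are byte-reproducible under a fixed seed. The headline metric is the mean
AUC across folds (PCC for quantitative tasks); AUC uses the rank/U-statistic
convention (ties count 1/2), making it invariant under monotone transforms
of the scores and equal to the trapezoidal area over unique thresholds.

## Saliency-based biomarkers

For categorical models, saliency is the gradient of the *positive-class
logit* (pre-softmax) with respect to every input entry — the pre-softmax
choice avoids vanishing gradients when predictions saturate. Per feature,
gradients collapse in two steps:

1. channel collapse: max over encoding channels of |gradient| (a one-hot
   feature gets one score, never five);
2. sample aggregation: mean over samples (or max, by flag).

Raw gradient magnitudes are not comparable across branches: a one-hot
genotype branch feeds larger dense layers per feature and systematically
carries larger input gradients than a z-scored expression branch, so a
global ranking of raw values is dominated by whichever layer has the larger
gradient scale, not by signal. Each layer's aggregated saliencies are
therefore divided by that layer's median before ranking (`layer_scale=
"median"`, `"none"` to disable); the calibration used is recorded in the
report metadata. Scores convert to dense ranks (rank 1 = highest, ties
share a rank, no gaps). Top-k selection includes boundary ties; a
threshold-based selection is also available. Non-gene markers (CpGs, SNPs,
CNV segments) map to their annotated neighboring gene (BED-like, 0-based
half-open intervals); several markers mapping to one gene keep the best
rank. Baseline importances (|coefficients| for linear models, impurity for
trees/forests, seeded permutation importance for the RBF SVM, which has no
per-feature coefficients) flow through the same report format after summing
channel-level scores per feature.

## Over-representation analysis

The biomarker stage produces an unranked gene list, so enrichment is the
hypergeometric upper tail: for universe size U, a set with K members in the
universe, a query of n genes with k overlapping, p = P(X ≥ k),
X ~ Hypergeom(U, K, n). Query genes outside the universe are dropped with a
warning; sets with no universe member are skipped. Benjamini–Hochberg
adjusts across sets. The default universe is the caller's choice (the CLI
uses the union of GMT members plus the query); a universe restricted to the
measured, gene-mapped features is the recommended practice. A ranked,
running-sum GSEA variant is deliberately out of scope.

Note the discreteness of the hypergeometric: with small sets the achievable
p-values are a coarse grid and P(p ≤ 0.05) under the null sits below 0.05.
The null-calibration check therefore uses sets of ~100 genes in a universe
of 1000, where the grid is fine near the usual thresholds.

## Bayesian hyperparameter search

The automated strategy is sequential model-based optimization. Trials map
into the unit cube (log-scaled where declared); after a random warm-up
(max(4, budget/4) trials), a Gaussian-process surrogate (Matern-5/2,
normalized targets) is refitted on completed trials and the next
configuration maximizes expected improvement over 256 seeded candidate
draws. Failed trials are recorded without a value, never become the best,
and do not stop the search; everything replays trial-for-trial under a
fixed seed. The default search space (learning rate log-uniform 1e-4…1e-2,
dropout 0…0.5, filters 8…64, kernel 2…8, FC width 16…128, batch
{16,32,64}) is a package choice, user-editable. The alternative strategies
— documented defaults (`default_config`) and manual overrides — need no
optimizer.

## The synthetic benchmark

The generator emulates the minimal statistical structure the models assume:
a shared cohort, most features uninformative, a small planted subset
differing between classes.

- Continuous layers: null features i.i.d. N(0, 1); planted features mean-
  shifted by the effect size δ (in sd units) in the positive class.
- SNP/CNV layers: per-feature category frequencies drawn once from a
  Dirichlet(5·1); planted features mix a fraction w = 0.15·δ of the
  positive-class distribution onto one randomly chosen category (error if
  w > 0.95). At δ = 2 this is a 30% total-variation shift — detectable but
  deliberately weaker than the continuous signal.
- Missingness uniform at a configurable rate (NaN for continuous, the
  `missing` token for SNPs; CNV stays complete, matching its no-imputation
  contract).
- Quantitative labels: δ-weighted mean of the planted features plus N(0, 1)
  noise.

A JSON manifest records the planted IDs, and `manifest_check` computes
precision@k / recall@k of any marker report against it. What the generator
does *not* emulate: linkage disequilibrium and allele-frequency spectra,
copy-number segment correlation along chromosomes, methylation beta-value
distributions, feature–feature correlation, batch effects. Passing the
benchmark therefore shows the pipeline recovers clean additive signal —
not that it handles the correlation structure of real cohorts.

Benchmark scale used by the test suite and the acceptance script: three
layers (expression 1000 features/10 planted, SNP 500/5, CNV 200/5),
n = 300, δ = 2, 5-fold CV, with training capped at 20 epochs (patience 6)
— enough for the multi-CNN to reach fold AUCs ≈ 0.95–0.99 in a few seconds
per fold on one CPU. A univariate-AUC ranking serves as the oracle that the
planted signal is recoverable at all; the CNN's saliency top-10 is compared
against the same ground truth.

## Numerical conventions and degenerate inputs

- AUC ties: rank/U-statistic formulation (deterministic, no threshold
  sweep ambiguity). PR curves: step convention with endpoints included.
- PCC with a constant prediction returns 0 (no linear association) rather
  than NaN; constant *truth* is an error for both PCC and R².
- A CV fold whose test part holds one class is skipped with a warning; all
  folds skipped is an error.
- Dense layers and convolutions initialize He-style (N(0, √(2/fan_in)));
  kernels longer than a branch's feature axis clamp to the axis length, so
  very small layers still build.
- Tuning trials that raise score as failed (−∞ for best-tracking purposes);
  the GP fits only completed trials.

## Limitations

- Multi-class (> 2) softmax heads are structurally supported but untuned;
  the shipped defaults target binary and quantitative phenotypes.
- The numpy training loop is single-threaded BLAS-bound; it is sized for
  cohorts of hundreds of samples and ~10³–10⁴ features per layer, not for
  genome-wide SNP panels in the millions.
- Vanilla gradients are the only saliency variant; gradient×input and
  smoothed gradients are not implemented.
- No probabilistic imputation, batch-effect correction, grouped/nested CV,
  or multi-objective tuning.
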