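# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic benchmark, and the limitations of `combistat`.

## Data model

The pipeline operates on an `ExpressionMatrix`: proteins × samples, float
values with NaN as the explicit missing mask, and a `scale_tag`
(`raw`/`log2`/`log10`) recording the transform state so stages can enforce
their scale preconditions (e.g. median/quantile normalization require a
logged matrix; iRS and the glog transform consume raw intensities). Sample
metadata carries the class label per sample plus an optional batch/plex
label and reference-channel flag for iRS. Class sets, comparison names and
output orderings are sorted lexicographically, so runs are deterministic
and file names reproducible.

Zeros are treated as observed by default; `zero_as_missing` converts them,
since label-free exports use both encodings. The user must declare whether
an input matrix is raw or pre-logged — the file itself cannot tell.

## Normalization

* **Median** — each sample is shifted additively (log scale) so its
  observed median equals the grand median of the original per-sample
  medians. Equivalent to scale normalization on the raw scale. Idempotent;
  leaves the missing mask untouched.
* **Quantile** — every sample's observed values are forced onto the common
  reference distribution (the mean across samples of each order statistic).
  With missing values, observed values are ranked within each sample and
  the reference is built by interpolating each sample's sorted observed
  values onto a grid of length equal to the largest observed count; ties
  within a sample receive the mean of the reference values at their tied
  ranks. On a complete matrix this is textbook quantile normalization
  (identical sorted multisets across samples, exactly).
* **iRS (internal reference scaling)** — for multi-batch labeled (TMT /
  iTRAQ) designs. Per protein and batch a reference abundance is the mean
  of the flagged reference channels, or of all the batch's samples when
  none are flagged (a documented pseudo-reference convention; with equal
  batch sizes it yields the same scaling factors as the row-sum
  convention). The geometric mean of the per-batch references is the
  target; every sample in a batch is multiplied by target/reference for
  that protein, on the raw scale. Proteins unobserved in a batch's
  reference stay missing there. Requires ≥ 2 batches.
* **vsn-glog** — a simplified variance-stabilizing normalization, not a
  re-implementation of the vsn2 package. Each sample is affinely
  calibrated, then transformed with the generalized log
  h(x) = arsinh((x − a_s)/b_s). Offsets/gains (a_s, g_s) are estimated by
  iterating a least-trimmed-squares affine fit (iterated 75 %-trimmed OLS)
  of each sample against the row means of the calibrated matrix until the
  largest parameter change is < 1e-6 (max 50 iterations). The glog scale is
  the additive/multiplicative noise ratio σ_add/σ_mult, with σ_add taken
  from the residual SD of the lowest-intensity quintile and σ_mult from the
  residual CV of the highest. Output is divided by ln 2 so downstream fold
  changes remain in log2 units. Calibration uses complete rows only and
  needs ≥ 10 of them.

The enforced stage order is log → normalize → impute (iRS and glog instead
start from raw intensities). Normalizing before imputation is a fixed
design choice: imputation parameters are then estimated on calibrated
samples, and imputed values can never leak into the normalization target.

## Imputation

* **Downshifted normal** (`normal_draw`) — models left-censored
  missing-not-at-random label-free data: missing cells in sample *s* are
  drawn from Normal(μ_s − shift·σ_s, (width·σ_s)²) with μ_s, σ_s the
  sample's **observed** mean and SD. Defaults shift = 1.8, width = 0.3 (the
  de-facto convention for this method); both are flags. Moments are per
  sample, matching the per-run censoring mechanism.
* **kNN** (`knn`, default k = 10) — neighbours are proteins, not samples,
  because proteomics matrices have proteins ≫ samples. Distance is
  Euclidean over jointly observed samples, rescaled by the overlap count so
  sparsity does not shrink distances. Donors missing the target sample are
  skipped for the next nearest; a protein with no usable donor falls back
  to its row mean. Deterministic.
* **Iterative forest** (`iterative_forest`) — missForest-style chained
  imputation over samples: initialize missing cells at row means, then
  sweep the samples in increasing missingness order, regressing each on all
  others with a 100-tree random forest fit on its observed rows and
  re-predicting its missing cells. Sweeps stop at the first increase of the
  normalized squared change in imputed values (or `max_iter` = 10),
  returning the previous iterate. A simplification of the R missForest
  algorithm, not bit-compatible with it.

All methods leave observed cells bit-identical and return a complete
matrix or raise. Differential testing refuses matrices with missing
values: imputation is a mandatory stage, which keeps the per-protein
residual degrees of freedom uniform and the moderated-t machinery simple.

## Combinatory comparison enumeration

Stage one emits all C(n,2) single-class pairs. Stage two enumerates every
two-block set partition {T1, T2} of the class set S — disjoint, non-empty,
jointly covering S — pools each block, and drops anything stage one already
produced (only the singleton–singleton bipartition at n = 2). The superset
{S} and the partition into n singletons are not two-block partitions and
never appear. This yields 2^(n−1) − 1 grouped comparisons for n > 2 and
totals 1, 6, 13, 25, 46 for n = 2…6. The grouped stage is inherently
exponential in n, so plans are capped (default 1000 comparisons ≈ 11
classes) with an error advising explicit selection rather than silent
truncation. Non-covering grouped pairs (e.g. A+B vs C with D left out) are
deliberately not generated; the covering condition is what separates the
grouped stage from an unbounded enumeration of all disjoint subset pairs.

Comparison names are deterministic: classes joined by `+` within a group,
groups joined by `_vs_`, the smaller group (the "class of interest" side)
first, ties broken lexicographically. "Contrast others" labels the pooled
complement *Others*.

## Differential testing

Cell-means two-group model per protein: logFC = mean(A) − mean(B) (log2;
log10 inputs are converted by log2(10)), pooled variance s², residual df
d = n_A + n_B − 2, SE factor v = 1/n_A + 1/n_B. Grouped comparisons pool
their member classes into one cell. Each group needs ≥ 2 samples.

Empirical-Bayes moderation follows the standard hierarchical model
(s² | σ² ~ σ²·χ²_d/d with scaled-inverse-chi-square prior σ² ~ s0²·d0/χ²_d0).
Hyperparameters come from the method of moments on e = log s²:
the excess of Var(e) over trigamma(d/2) is inverted through the trigamma
function (Brent root-find, tolerance 1e-12) to get d0/2, and
log s0² = mean(e) − digamma(d/2) + digamma(d0/2) + log(d/d0). Zero
variances are floored at 1e-8 before the fit; without excess dispersion d0
is capped at 1e6 and the t reference becomes normal. Moderated variance
s̃² = (d0·s0² + d·s²)/(d0 + d); p-values are two-sided Student t on d + d0
df. d0 = 0 reduces exactly to the ordinary pooled two-sample t (verified
against an independent implementation to 1e-10).

Benjamini–Hochberg step-up adjustment is applied **per comparison** (the
topTable convention), not pooled across the plan. Significance requires
both |logFC| ≥ min_abs_logfc and q ≤ max_adj_p; direction "up" means
higher in group A. Tables sort by P, ties by |logFC| then protein id.
Hyperparameters are re-fit per comparison on its own sample subset, since
different pooled groups have different residual structures; a single
global fit would be marginally more stable but couples unrelated
comparisons. A comparison failing its preconditions (e.g. a single-replicate
class) is recorded as an error and the rest of the plan still runs.

## Projection and visualization tables

PCA is an SVD of the sample × protein matrix with each protein centered
across samples (optional unit-variance scaling; off by default because
abundances are already log/normalized). Sign convention: the
largest-magnitude loading of each component is positive. Subset PCA
restricts to a functional protein class list (identifier-per-line text
files, matched case-insensitively, ≥ 3 matches required) — the
protease/kinase/transcription-factor view of the data. Volcano tables,
top-N DEP extracts (default 50, optionally up/down only) and hierarchical
clustering orders (Euclidean distance, average linkage by default) are
emitted as plain tables; `render_plots` writes static PNGs with every
underlying table alongside as CSV, degrading to table-only on rendering
failure.

## Synthetic spike-in benchmark

The generator emulates a spike-in experiment, where ground truth is known
by construction. Per protein, a log2 baseline ~ Normal(23, 1.5²); classes
A/B/C with 4 replicates each; 10 % of proteins receive a +1.5 log2 effect
in one randomly chosen class; replicate noise ~ Normal(0, 0.3²); optional
per-class multiplicative batch shifts. Missingness is either MCAR or —
the default — left-censored MNAR: P(missing | x) = 1/(1 + exp((x − τ)/0.5))
with τ root-solved so the expected missing fraction equals `missing_rate`
(default 0.1). These defaults are the package's reference scenario:
realistic label-free abundance ranges, replicate CVs and missingness for a
three-condition design at desk scale. Identical seeds give bit-identical
outputs.

`truth_confusion` scores a result against the truth: a protein is a
positive when the magnitude of its expected contrast under the truth
(effect diluted by pooled-group size for grouped comparisons) reaches the
fold-change call cutoff. Recovery is therefore evaluated on the
single-class pairs, where truth labels at the call cutoff are unambiguous —
in a 1-vs-2 pooling a 1.5-log2 effect dilutes to 0.75, below the default
cutoff, so grouped comparisons have no well-defined positive set there.
On the reference scenario the full pipeline (log2 → quantile →
downshifted-normal imputation → moderated-t DEA) reaches pooled
sensitivity ≈ 0.93–0.95 at empirical FDR < 0.02 across five seeds, and a
null scenario (no spiked effects) yields essentially no calls at q ≤ 0.05.

What the generator does **not** emulate: peptide-to-protein rollup, TMT
ratio compression, interference, correlated protein modules, or
batch-by-class confounding. Passing benchmarks here demonstrates the
statistical machinery is correct and calibrated under the stated model,
not that any real dataset will behave as cleanly; in particular the
sensitivity figure degrades when true effects sit at low intensity where
censoring destroys the signal — visible in the benchmark as the residual
~5 % of spiked proteins whose values are mostly imputed.

## Numerical choices and degenerate inputs

* Trigamma inversion by Brent bracketing on [1e-8, 1e8]; d0 cap 1e6.
* Residual-variance floor 1e-8 (possible after constant imputation).
* Quantile reference uses linear interpolation between order statistics;
  a sample with a single observed value maps to the reference start.
* BH is vectorized step-up with a reverse cumulative minimum; inputs
  outside [0, 1] are rejected.
* Empty groups, single-replicate groups, all-missing proteins, unknown
  class labels, non-numeric CSV cells and duplicate identifiers all raise
  typed errors naming the offending entity.
* The hierarchical-clustering leaf order uses scipy's deterministic
  dendrogram ordering; permuting input rows preserves tree topology
  (cophenetic distances) though not necessarily the leaf sequence.

## Known limitations

* Single-factor designs only: no covariates, blocking, duplicate
  correlation, robust/trend eBayes, or TREAT-style thresholded tests.
* vsn-glog and iterative forest are documented simplifications of vsn2 and
  missForest, suitable for the pipeline's purposes but not drop-in
  replacements for the R packages.
* Quantile normalization's missing-value extension assumes the observed
  ranks are representative; under heavy asymmetric MNAR it biases the low
  tail.
* The grouped enumeration is exponential in the number of classes; the cap
  makes this explicit instead of hiding it.
* Enrichment analysis is out of scope: the tool exports ranked gene-symbol
  lists formatted for external services (DAVID / ShinyGO / STRING), nothing
  more.
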