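# Methods

This note documents the models, defaults and numerical choices behind
`omicsfuse`, and what the synthetic cohorts do and do not establish about
real data.

## Similarity network fusion

Each preprocessed layer is z-scored per analyte (zero-variance analytes map
to zero rows) and converted to a sample affinity graph with a scaled Gaussian
kernel on Euclidean distances:

    eps(i,j) = (mean_k(i) + mean_k(j) + d(i,j)) / 3
    W(i,j)   = exp(-d(i,j)^2 / (mu * eps(i,j)))

where `mean_k(i)` is the mean distance from sample i to its k nearest
neighbors. `mu` multiplies the *adaptive* scale `eps` rather than acting as an
absolute bandwidth — the convention of the reference SNF implementations, in
whose recommended range (0.3–0.8) the stability search operates. Coincident
samples are handled by flooring `eps` at 1e-12.

Fusion follows the cross-diffusion scheme: per view, a dense "global" kernel
`P(i,j) = W(i,j) / (2 Σ_{l≠i} W(i,l))` (diagonal 1/2) and a sparse kNN
"local" kernel `S` (row-normalized over each sample's k nearest neighbors).
For t = 20 iterations, `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ`, then symmetrize
and renormalize — in that order, so every view kernel is exactly
row-stochastic after each iteration. The fused network is the mean of the
final kernels, symmetrized; its row sums are therefore only approximately 1
(within a few percent), which is immaterial downstream because spectral
clustering is invariant to symmetric renormalization and uniform scaling.
Fusion requires at least two views; samples missing any layer are excluded
from fusion and handled later by the incomplete-sample classifier.

## Spectral clustering and the eigengap

Clustering uses the normalized-affinity embedding (Ng–Jordan–Weiss): top-C
eigenvectors of `D^{-1/2} W D^{-1/2}`, rows normalized to unit length,
k-means with 20 restarts and a fixed seed, labels renumbered by descending
cluster size. The cluster count is the argmax of `λ_{C+1} − λ_C` over the
ascending eigenvalues of the random-walk Laplacian `I − D^{-1}W`, searched
over C ∈ [2, 10]; ties go to the smaller C (so a degenerate uniform affinity
returns 2). Whether the original analyses used k-means or a discretization
step internally is not derivable from their description; k-means with fixed
seed and multiple restarts was chosen for determinism, and the stability and
recovery tests are insensitive to the choice. The eigengap is evaluated on
the fused network (the matrix that determines the final clustering).

## Stability-based hyperparameter selection

For each (mu, k) grid cell: fuse and cluster the full data (C from the
eigengap on that cell's fused network), then draw `n_subsamples` random
subsets of `ceil(0.8 n)` samples without replacement, re-fuse and re-cluster
each at the same C, and score against the full-data clustering restricted to
the subsample with adjusted mutual information. The selected cell maximizes
mean AMI; ties prefer smaller k, then smaller mu. Each cell derives its own
RNG stream from (seed, mu, k), so cells are independently reproducible.

AMI uses the exact hypergeometric expectation of mutual information under
the permutation null and the arithmetic-mean-of-entropies normalizer. Both
numerator and denominator are floored at ±machine-eps with sign preserved,
so the degenerate all-singleton case (where E[MI] equals the maximum)
resolves to 1 for identical partitions — matching the behavior of the
standard library implementations it is tested against.

## Preprocessing

All printed thresholds are applied with strict inequality (total < 500,
zero fraction > 0.80, mean < 10, censored fraction > 0.5), so boundary
analytes survive; this is stated explicitly so independent implementations
agree record-for-record.

The variance-stabilizing step is median-of-ratios size factors followed by
`log2(x/sf + 1)` rather than a dispersion-spline VST: downstream fusion
consumes per-analyte z-scores, which absorb monotone scale differences, and
the approximation keeps one code path for both count layers. Batch
adjustment is a single empirical-Bayes location-scale scheme on the log
scale for all four layers (per analyte: regression on batch indicators plus
preserve covariates, parametric shrinkage of per-batch location/scale toward
across-analyte moments, removal of the batch component, restoration of the
covariate part). Two consequences are worth knowing: (i) with a single batch
the layer is returned unchanged; (ii) shrinkage leaves a small absolute
residual in per-analyte batch means (on the order of the batch-mean sampling
noise), so "batch means equalized" holds relative to the removed shift, not
to machine precision. PCA outlier removal (|score| > 4 SD on PC1 or PC2)
applies to the RNA and protein layers by default and can be toggled per
layer; any sample flagged in any fused layer is removed from all layers so
the fusion sample set stays common. Metabolite censored values are imputed
to the analyte's minimum measured value; protein censored values are used
as is.

## Cross-validated cluster prediction

The repeated CV (10 repeats × 10 stratified folds) re-fits everything that
could leak labels inside each training fold: the top-quartile variance
filter, the per-layer affinities, the fusion, and the spectral clustering.
Test folds receive labels by propagation over the fused train+test graph
(one-hot training labels diffused through the row-normalized affinity with
training rows re-clamped, tolerance 1e-6, max 1000 iterations), and each
split's labels are aligned to the full-data reference clustering by the
agreement-maximizing permutation (Hungarian assignment; verified against
exhaustive search for C ≤ 8 in tests). A training fold that loses a cluster
is redrawn (bounded retries). One deliberate simplification: the λ path is
computed once from the full feature matrix (glmnet-style data-driven
maximum, log-spaced, default 10 values to a 1e-3 ratio) so that sparsity is
comparable across splits; training-fold quantities remain functions of
training data only.

The classifier is multinomial logistic regression with an elastic-net
penalty (saga solver). The penalty is per-coefficient rather than grouped
over classes (the grouped variant is not available in the solver used); the
selection rule is unchanged — a feature counts as selected when any class
coefficient is nonzero. The final (α, λ) is the sparsest pair whose mean
balanced accuracy is within one SD (of the best pair's per-split accuracies)
of the best mean; ties prefer larger λ. The same 100 splits serve both
hyperparameter selection and performance estimation, which mildly flatters
the reported accuracy; this mirrors the single-grid repeated-CV design the
pipeline reproduces and is acknowledged rather than corrected. Samples with
incomplete omics are assigned by refitting the chosen model on all
complete-case samples using only the stable features, with absent features
mean-imputed (zero after training standardization).

## BIC model comparison

Each competing labeling (C clusters; 6 disease groups; the merged 4-level
disease grouping that pools the two control groups and pools FGR+HDP with
severe PE) is a saturated categorical logistic model, so its MLE is closed
form: the fitted probability per level is the observed positive fraction,
with 0·ln 0 = 0 for perfectly separated levels. This is exactly the
likelihood an iterative solver would reach (tested to 1e-6 on non-separated
fixtures) and avoids separation failures. `BIC = p·ln(n) − 2·lnL` with
p = number of levels; no covariates enter, matching the comparison being
reproduced. Evidence grades: ΔBIC < 2 weak, 2–6 positive, > 6 strong (the
first cutoff is the one used in the source analysis; the others are the
conventional extension).

## Synthetic cohorts

`generate_cohort` emulates the study conditions: four layers, four clusters
(default proportions 0.38/0.27/0.22/0.13, largest cluster dominated by
controls), negative-binomial counts (variance = μ + μ²/θ; θ = 8 for RNA,
5 for miRNA) with log-normal library sizes (σ = 0.3), Gaussian log-scale
protein (453 analytes, matching a five-panel targeted assay) and metabolite
layers, 25 markers per cluster per layer at a default effect of 2 SD, two
batches with 0.5-SD log-scale shifts, gestational-age means of 39/33/31/38
weeks per cluster (σ = 2), a cluster→disease confusion matrix in which each
cluster is dominated by one syndrome, histopathology outcomes drawn from
per-cluster logistic models (one lesion strongly enriched in the
PE-dominated cluster), and per-layer missingness (9%/9%/1.5%/2%) yielding
roughly a fifth of samples incomplete — the generator's defaults are the
conditions under which all calibration claims are made.

Marker effect sizes are in units of the analyte's total log-scale SD
(including dispersion and library-size spread for counts), so a 2-SD marker
has one-vs-rest AUROC near Φ(2/√2) ≈ 0.92 in every layer. Detection limits
are per-analyte quantiles of the generated values (default 5–10% censored),
with a small fraction of "poorly detected" analytes censored at the 60%
quantile so the >50%-censored filter always has cases to act on. Ground
truth (cluster labels, marker ownership) is stored outside the sample sheet
so the pipeline cannot consume it.

Two focused generators support calibration studies: `planted_feature_cohort`
(two Gaussian layers, a balanced 2-cluster structure carried by 5
informative analytes among 200 decoys — 2 clusters because the
feature-recovery question is about sparse selection under in-fold
re-clustering, and a 2-cluster geometry keeps that re-clustering stable at
the stated 2-SD effect) and `outcome_cohort` (cluster/disease labels plus a
binary outcome generated from either, for the BIC consistency study).

What the synthetic cohorts do **not** emulate: analyte–analyte correlation
(analytes are conditionally independent given cluster, batch and library
size), gestational-age effects on analytes, realistic metabolite pathway
structure, heavy-tailed protein noise, or any specific real analyte. Passing
tests therefore demonstrate that the algorithms recover structure of the
assumed statistical shape at the assumed effect sizes — not that any real
cohort contains such structure.

## Problem sizes and determinism

The test suite and the acceptance script run cohorts of n = 100–250 with
300–1000 analytes per layer, 20–50 stability subsamples and 100 CV splits —
sizes chosen so a full run completes in minutes on one CPU while every
calibration claim is still measured, not assumed. All randomness flows from
a single seed through named SeedSequence spawn keys (per stage, grid cell,
split), so any stage can be reproduced in isolation; identical configs give
byte-identical outputs.

## Known limitations

- The fused network's row sums are approximate (see above); consumers should
  not treat it as a transition matrix without renormalizing.
- The one-SD model-selection rule uses the best pair's SD only, and the CV
  reuses the same splits for selection and reporting (documented optimism).
- Label propagation builds the combined graph with z-scores computed on
  train+test jointly; training-fold quantities are unaffected, but the
  propagation itself (like any transductive method) uses test features.
- The empirical-Bayes batch adjustment assumes roughly Gaussian log-scale
  values within batch; it is applied after the count transform rather than
  on raw counts, trading the count-specific variant for one code path.
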