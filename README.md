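# omicsfuse

Unsupervised integration of multi-omics cohorts by **similarity network
fusion (SNF)**, built for studies where several molecular layers — RNA and
miRNA counts, targeted protein panels, metabolite abundances — are measured
on the same samples and the goal is to find disease-independent sample
subgroups and ask whether they explain clinical outcomes better than the
predefined diagnoses do. The motivating setting is placental multi-omics in
common obstetrical syndromes (preeclampsia, fetal growth restriction,
spontaneous preterm delivery), but nothing in the code is specific to it.

## What it does

Given per-datatype analyte × sample matrices and a clinical sample sheet,
the pipeline:

1. **Preprocesses** each layer with the field's standard rules: count filters
   (RNA analytes with total < 500 or > 80% zeros dropped; miRNA mean < 10
   dropped), size-factor normalization + log transform for counts,
   limit-of-detection filtering (> 50% censored dropped) with
   minimum-measured-value imputation for metabolites, 4-SD PCA outlier
   removal, empirical-Bayes batch adjustment that preserves clinical
   covariates, and a top-quartile variance filter.
2. **Fuses** the layers: per layer, a scaled Gaussian kernel on Euclidean
   distances over z-scored analytes gives an affinity graph
   `W(i,j) = exp(−d²(i,j) / (μ·ε(i,j)))` with the adaptive scale
   `ε(i,j) = (mean kNN distance of i + mean kNN distance of j + d(i,j))/3`;
   cross-diffusion `P_v ← S_v · mean_{u≠v}(P_u) · S_vᵀ` (t = 20 iterations,
   sparse kNN kernels `S_v`) merges the graphs into one fused network.
3. **Clusters** the fused network by normalized-Laplacian spectral clustering,
   with the cluster count C chosen by the eigengap heuristic
   (argmax of λ_{C+1} − λ_C over the random-walk Laplacian spectrum).
4. **Selects hyperparameters** (μ, k) by clustering stability: for each grid
   cell, 50 random 80% subsamples are re-fused and re-clustered, and scored
   by adjusted mutual information (exact hypergeometric E[MI], mean-entropy
   normalizer) against the full-data clustering; the most stable cell wins.
5. **Ranks cluster markers** by one-vs-rest AUROC (Mann–Whitney, midrank
   ties), keeping the top 10 per cluster and datatype.
6. **Cross-validates a cluster classifier** without label leakage: in each of
   10×10 repeated stratified CV splits, the variance filter, fusion and
   spectral clustering are re-fit on training samples only; test-fold labels
   come from label propagation over the train+test affinity graph; labels are
   permutation-matched to the full-data clustering; an elastic-net multinomial
   regression is fit over an (α, λ) grid, the final pair being the sparsest
   model within one SD of the best balanced accuracy. Features selected in
   ≥ 50 of 100 splits are declared stable, and a refit on the stable features
   assigns clusters to samples with incomplete omics.
7. **Compares labelings by BIC**: per binary histopathology outcome, saturated
   categorical logistic models for the C clusters, the 6 disease groups, and
   a merged 4-level disease grouping are fit in closed form and ranked by
   `BIC = p·ln(n) − 2·lnL`; a difference < 2 is graded weak evidence.

A **synthetic cohort generator** (`omicsfuse.synthetic`) produces all four
layers with planted cluster structure — negative-binomial counts with
log-normal library sizes, Gaussian log-scale targeted panels with detection
limits, batch effects, gestational age correlated with cluster, a disease
label drawn from a cluster→disease confusion matrix, per-cluster logistic
histopathology outcomes, and per-layer sample missingness — so the entire
pipeline is testable with known ground truth.

## Worked example

```python
import omicsfuse as of
from omicsfuse.core import SNFHyperparams
from omicsfuse.preprocess import preprocess_bundle
from omicsfuse.snf import fuse_layers, eigengap_select, spectral_cluster
from sklearn.metrics import adjusted_rand_score

spec = of.CohortSpec(n_samples=200, seed=3,
                     missingness_rates={k: 0.0 for k in ("rna", "mirna", "protein", "metabolite")})
bundle = of.generate_cohort(spec)                      # 4 layers, 4 planted clusters
layers, report = preprocess_bundle(bundle.layers, bundle.sheet,
                                   preserve=["disease_group", "gestational_age"])
fused = fuse_layers(list(layers.values()), SNFHyperparams(mu=0.5, k=20))
C = eigengap_select(fused, 2, 10)
clusters = spectral_cluster(fused, C, seed=0)
truth = bundle.true_clusters.loc[clusters.sample_ids]
print(C, adjusted_rand_score(truth, clusters.labels))
```

prints

```
4 1.0
```

i.e. the eigengap recovers the planted cluster count (4) and spectral
clustering of the fused network reproduces the withheld ground-truth
partition exactly (adjusted Rand index 1.0) at the default 2-SD marker
effect size.

The same run from the shell:

```bash
omicsfuse simulate --n-samples 200 --seed 3 --out cohort/
omicsfuse cluster --from cohort/ --mu 0.5 --k 20 --out run/
omicsfuse run-all --config config.yaml --out run/   # full pipeline from YAML
```

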