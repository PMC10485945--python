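"""Leakage-free repeated cross-validation of an elastic-net multinomial
classifier that predicts fused-network cluster labels.

Each of the n_repeats x n_folds training splits re-runs the whole clustering
pipeline on training samples only: per-layer top-quartile variance filtering,
network fusion and spectral clustering are all fit in-fold, test-fold labels
are assigned by label propagation over the train+test affinity graph, and the
split's labels are permuted to best match the full-data reference clustering
so labels are comparable across splits. The elastic net is then fit on
standardized training features over an (alpha, lambda) grid; the final pair
is the sparsest model whose mean balanced accuracy is within one SD of the
best, and features selected (any nonzero class coefficient) in at least
`selection_threshold` of the splits are called stable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .core import (
    ClusterAssignment,
    ContractError,
    OmicsLayer,
    SampleSheet,
    SNFHyperparams,
    derive_int_seed,
)
from .markers import auroc
from .preprocess import top_variance_filter
from .snf import eigengap_select, fuse_layers, propagate_labels, spectral_cluster


# ---------------------------------------------------------------------------
# label matching
# ---------------------------------------------------------------------------

def match_cluster_labels(
    labels: ClusterAssignment, reference: ClusterAssignment
) -> ClusterAssignment:
    """Relabel `labels` by the permutation of {1..C} that maximizes exact-match
    agreement with `reference` on their shared samples (Hungarian assignment).

    If the cluster counts differ, matching runs on the smaller count and
    surplus labels stay distinct (with a warning).
    """
    shared = [s for s in labels.sample_ids if s in set(reference.sample_ids)]
    if not shared:
        raise ContractError("no overlapping samples to match on")
    ref_of = dict(zip(reference.sample_ids, reference.labels))
    a = np.array([dict(zip(labels.sample_ids, labels.labels))[s] for s in shared])
    b = np.array([ref_of[s] for s in shared])
    c_lab, c_ref = labels.C, reference.C
    if c_lab != c_ref:
        warnings.warn(
            f"cluster counts differ ({c_lab} vs {c_ref}); matching on the smaller count"
        )
    size = max(c_lab, c_ref)
    agreement = np.zeros((size, size))
    for i in range(1, c_lab + 1):
        for j in range(1, c_ref + 1):
            agreement[i - 1, j - 1] = np.sum((a == i) & (b == j))
    row, col = linear_sum_assignment(-agreement)
    perm = {int(r) + 1: int(c) + 1 for r, c in zip(row, col)}
    new_labels = np.array([perm[l] for l in labels.labels])
    return ClusterAssignment(labels.sample_ids, new_labels, max(c_lab, c_ref), labels.source)


def brute_force_match(labels: np.ndarray, reference: np.ndarray, C: int) -> np.ndarray:
    """Exhaustive C! search for the agreement-maximizing relabeling (test oracle)."""
    best_perm, best_agree = None, -1
    for perm in permutations(range(1, C + 1)):
        mapped = np.array([perm[l - 1] for l in labels])
        agree = int(np.sum(mapped == reference))
        if agree > best_agree:
            best_agree, best_perm = agree, perm
    return np.array([best_perm[l - 1] for l in labels])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def multiclass_auc(prob: np.ndarray, truth) -> float:
    """Pairwise-averaging multiclass AUC: the mean over ordered class pairs
    (i, j) of the AUROC of P(class i) separating class-i from class-j samples."""
    prob = np.asarray(prob, dtype=float)
    truth = np.asarray(truth)
    if prob.ndim != 2 or prob.shape[0] != truth.shape[0]:
        raise ContractError("prob must be samples x classes aligned with truth")
    if np.any(np.abs(prob.sum(axis=1) - 1.0) > 1e-6):
        raise ContractError("probability rows must sum to 1")
    classes = np.arange(1, prob.shape[1] + 1)
    present = set(np.unique(truth).tolist())
    aucs = []
    for i in classes:
        for j in classes:
            if i == j:
                continue
            if i not in present or j not in present:
                warnings.warn(f"class pair ({i},{j}) missing from truth; skipped")
                continue
            mask = (truth == i) | (truth == j)
            aucs.append(auroc(prob[mask, i - 1], truth[mask] == i))
    if not aucs:
        raise ContractError("no evaluable class pairs")
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def build_feature_matrix(
    layers: list[OmicsLayer],
    sheet: SampleSheet,
    sample_ids: list[str],
    clinical: tuple[str, ...] = ("gestational_age",),
) -> pd.DataFrame:
    """Concatenate omics analytes with clinical covariates into a samples x
    features frame. Categorical covariates are one-hot encoded with the
    reference (first sorted) level dropped."""
    blocks = []
    for layer in layers:
        sub = layer.subset_samples(sample_ids)
        blocks.append(
            pd.DataFrame(sub.values.T, index=sample_ids, columns=sub.analyte_ids)
        )
    meta = sheet.frame.loc[sample_ids]
    for cov in clinical:
        col = meta[cov]
        if col.dtype.kind in "biufc":
            blocks.append(col.to_frame(f"clinical:{cov}").astype(float))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=f"clinical:{cov}")
            dummies = dummies.iloc[:, 1:]  # drop reference level
            blocks.append(dummies.astype(float))
    out = pd.concat(blocks, axis=1)
    if out.isna().any().any():
        raise ContractError("feature matrix contains missing entries")
    return out


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def glmnet_lambda_path(
    x: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced lambda path from the data-driven maximum
    lambda_max = max |X^T (Y - mean)| / (n * alpha)."""
    n = x.shape[0]
    classes = np.unique(y)
    ymat = (y[:, None] == classes[None, :]).astype(float)
    ymat -= ymat.mean(axis=0)
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    lam_max = np.abs(xs.T @ ymat).max() / (n * max(alpha, 0.01))
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# configuration / results
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetConfig:
    alpha_grid: list[float] = field(default_factory=lambda: [0.1, 0.5, 0.9])
    n_lambda: int = 10
    lambda_min_ratio: float = 1e-3
    n_repeats: int = 10
    n_folds: int = 10
    selection_threshold: int = 50
    max_iter: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid or self.n_lambda < 1:
            raise ContractError("alpha grid and lambda path must be nonempty")
        if any(not (0 < a <= 1) for a in self.alpha_grid):
            raise ContractError("alpha values must lie in (0, 1]")
        if self.selection_threshold > self.n_repeats * self.n_folds:
            raise ContractError("selection_threshold exceeds the number of splits")


@dataclass
class CVResult:
    chosen_alpha: float
    chosen_lambda: float
    split_table: pd.DataFrame  # split, balanced_accuracy, multiclass_auc
    selection_counts: pd.Series  # per feature, out of n_splits
    per_cluster_auc: dict[int, float]
    feature_names: list[str]
    n_splits: int
    C: int
    reference: ClusterAssignment

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(self.split_table["balanced_accuracy"].mean())

    @property
    def mean_multiclass_auc(self) -> float:
        # degenerate folds (single-class truth) are recorded as NaN
        return float(np.nanmean(self.split_table["multiclass_auc"]))

    def to_json(self, path=None) -> str:
        payload = {
            "chosen_alpha": self.chosen_alpha,
            "chosen_lambda": self.chosen_lambda,
            "n_splits": self.n_splits,
            "C": self.C,
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "mean_multiclass_auc": self.mean_multiclass_auc,
            "per_cluster_auc": {str(k): v for k, v in self.per_cluster_auc.items()},
            "splits": self.split_table.to_dict(orient="records"),
            "selection_counts": {
                k: int(v) for k, v in self.selection_counts.items() if v > 0
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def selection_frequency_csv(self, path) -> None:
        df = (
            self.selection_counts[self.selection_counts > 0]
            .sort_values(ascending=False)
            .rename("n_selected")
            .to_frame()
        )
        df.index.name = "feature"
        df.to_csv(path)


def select_stable_features(result: CVResult, threshold: int = 50) -> list[str]:
    """Features selected in >= threshold splits, sorted by count desc then name."""
    counts = result.selection_counts
    keep = counts[counts >= threshold]
    return list(keep.sort_index().sort_values(ascending=False, kind="mergesort").index)


# ---------------------------------------------------------------------------
# the repeated CV itself
# ---------------------------------------------------------------------------

def full_data_clustering(
    layers: list[OmicsLayer],
    snf_params: SNFHyperparams,
    *,
    variance_quantile: float = 0.25,
    C: Optional[int] = None,
    c_max: int = 10,
    seed: int = 0,
) -> ClusterAssignment:
    """Reference clustering: variance-filter, fuse, eigengap (unless C given),
    spectral-cluster the complete-case samples."""
    filtered = [top_variance_filter(l, variance_quantile) for l in layers]
    fused = fuse_layers(filtered, snf_params)
    if C is None:
        C = eigengap_select(fused, 2, min(c_max, fused.n_samples - 1))
    return spectral_cluster(fused, C, derive_int_seed(seed, "full-clustering"))


def _stratified_splits(labels: np.ndarray, config: ElasticNetConfig) -> list[tuple]:
    """n_repeats x n_folds stratified splits; a repeat whose training folds
    lose a cluster is redrawn (max 10 tries)."""
    splits = []
    all_clusters = set(np.unique(labels))
    for rep in range(config.n_repeats):
        for attempt in range(10):
            skf = StratifiedKFold(
                n_splits=config.n_folds,
                shuffle=True,
                random_state=derive_int_seed(config.seed, "fold", rep, attempt),
            )
            candidate = list(skf.split(np.zeros(len(labels)), labels))
            if all(set(labels[tr]) == all_clusters for tr, _ in candidate):
                splits.extend(candidate)
                break
        else:
            raise ContractError("could not build training folds covering every cluster")
    return splits


def repeated_cv_elastic_net(
    layers: list[OmicsLayer],
    sheet: SampleSheet,
    snf_params: SNFHyperparams,
    net_config: ElasticNetConfig,
    *,
    reference: Optional[ClusterAssignment] = None,
    variance_quantile: float = 0.25,
    clinical: tuple[str, ...] = ("gestational_age",),
) -> CVResult:
    """Repeated stratified CV with in-fold clustering and label propagation.

    `layers` must be preprocessed log-scale layers on a common sample set
    (complete cases); the variance filter is re-applied inside every training
    fold so no test information reaches any training-fold quantity.
    """
    ids = layers[0].sample_ids
    for l in layers[1:]:
        if l.sample_ids != ids:
            raise ContractError("layers must share a common sample set/order")
    if reference is None:
        reference = full_data_clustering(
            layers, snf_params, variance_quantile=variance_quantile, seed=net_config.seed
        )
    if reference.sample_ids != ids:
        raise ContractError("reference clustering must cover the layers' samples")
    C = reference.C
    ref_labels = reference.labels

    features_all = build_feature_matrix(layers, sheet, ids, clinical)
    feature_names = list(features_all.columns)
    lambda_paths = {
        alpha: glmnet_lambda_path(
            features_all.to_numpy(), ref_labels, alpha, net_config.n_lambda,
            net_config.lambda_min_ratio,
        )
        for alpha in net_config.alpha_grid
    }

    splits = _stratified_splits(ref_labels, net_config)
    n_splits = len(splits)
    pair_keys = [
        (ai, li)
        for ai in range(len(net_config.alpha_grid))
        for li in range(net_config.n_lambda)
    ]
    bal_acc = {key: np.empty(n_splits) for key in pair_keys}
    masks = {key: [] for key in pair_keys}
    probs = {key: [] for key in pair_keys}
    truths = {key: [] for key in pair_keys}

    for si, (tr_idx, te_idx) in enumerate(splits):
        tr_ids = [ids[i] for i in tr_idx]
        te_ids = [ids[i] for i in te_idx]
        # (i) variance filter on training samples only
        tr_layers, te_layers = [], []
        for layer in layers:
            tr = top_variance_filter(layer.subset_samples(tr_ids), variance_quantile)
            keep = tr.analyte_ids
            pos = {a: i for i, a in enumerate(layer.analyte_ids)}
            te = layer.subset_analytes([pos[a] for a in keep]).subset_samples(te_ids)
            tr_layers.append(tr)
            te_layers.append(te)
        # (ii) in-fold fusion + clustering
        fused_tr = fuse_layers(tr_layers, snf_params)
        tr_assign = spectral_cluster(fused_tr, C, derive_int_seed(net_config.seed, "cv", si))
        # (iii) propagate labels to the held-out fold
        propagated = propagate_labels(tr_layers, te_layers, tr_assign, snf_params)
        # (iv) permute split labels to match the full-data reference
        matched = match_cluster_labels(propagated, reference.restrict(tr_ids))
        label_of = dict(zip(matched.sample_ids, matched.labels))
        y_tr = np.array([label_of[s] for s in tr_ids])
        y_te = np.array([label_of[s] for s in te_ids])
        # (v) elastic net on standardized training features
        x_tr = features_all.loc[tr_ids].to_numpy()
        x_te = features_all.loc[te_ids].to_numpy()
        mean, sd = _standardize(x_tr)
        x_tr = (x_tr - mean) / sd
        x_te = (x_te - mean) / sd
        present = np.unique(y_tr)
        for ai, alpha in enumerate(net_config.alpha_grid):
            for li, lam in enumerate(lambda_paths[alpha]):
                clf = LogisticRegression(
                    penalty="elasticnet",
                    solver="saga",
                    l1_ratio=alpha,
                    C=1.0 / (lam * len(y_tr)),
                    max_iter=net_config.max_iter,
                    tol=1e-4,
                    random_state=derive_int_seed(net_config.seed, "saga", si, ai, li),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(x_tr, y_tr)
                pred = clf.predict(x_te)
                key = (ai, li)
                with warnings.catch_warnings():
                    # small test folds may miss a cluster; balanced accuracy
                    # over the present classes is still what we want
                    warnings.simplefilter("ignore")
                    bal_acc[key][si] = balanced_accuracy_score(y_te, pred)
                masks[key].append(np.any(clf.coef_ != 0, axis=0))
                p = np.zeros((len(te_ids), C))
                for ci, cls in enumerate(present):
                    p[:, int(cls) - 1] = clf.predict_proba(x_te)[:, ci]
                probs[key].append(p)
                truths[key].append(y_te)

    # final pair: sparsest within one SD of the best mean balanced accuracy
    means = {key: float(bal_acc[key].mean()) for key in pair_keys}
    best_key = max(pair_keys, key=lambda k: means[k])
    best_sd = float(bal_acc[best_key].std(ddof=1)) if n_splits > 1 else 0.0
    floor = means[best_key] - best_sd
    candidates = [k for k in pair_keys if means[k] >= floor]
    mean_nnz = {k: float(np.mean([m.sum() for m in masks[k]])) for k in candidates}
    chosen = min(
        candidates,
        key=lambda k: (
            mean_nnz[k],
            -lambda_paths[net_config.alpha_grid[k[0]]][k[1]],
            -net_config.alpha_grid[k[0]],
        ),
    )
    chosen_alpha = net_config.alpha_grid[chosen[0]]
    chosen_lambda = float(lambda_paths[chosen_alpha][chosen[1]])

    counts = pd.Series(
        np.sum([m.astype(int) for m in masks[chosen]], axis=0), index=feature_names
    )
    split_rows = []
    for si in range(n_splits):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                auc = multiclass_auc(
                    probs[chosen][si] / probs[chosen][si].sum(axis=1, keepdims=True),
                    truths[chosen][si],
                )
            except ContractError:
                # degenerate fold: propagated labels collapsed to one class
                auc = float("nan")
        split_rows.append(
            {
                "split": si,
                "balanced_accuracy": float(bal_acc[chosen][si]),
                "multiclass_auc": auc,
            }
        )
    # per-cluster one-vs-rest AUCs pooled over all test folds
    pooled_p = np.vstack(probs[chosen])
    pooled_y = np.concatenate(truths[chosen])
    per_cluster = {}
    for c in range(1, C + 1):
        if (pooled_y == c).any() and (pooled_y != c).any():
            per_cluster[c] = auroc(pooled_p[:, c - 1], pooled_y == c)
    return CVResult(
        chosen_alpha=chosen_alpha,
        chosen_lambda=chosen_lambda,
        split_table=pd.DataFrame(split_rows),
        selection_counts=counts,
        per_cluster_auc=per_cluster,
        feature_names=feature_names,
        n_splits=n_splits,
        C=C,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# final fit + prediction for samples with incomplete omics
# ---------------------------------------------------------------------------

@dataclass
class FittedClusterModel:
    classifier: LogisticRegression
    stable_features: list[str]
    means: pd.Series
    sds: pd.Series
    C: int


def fit_final_model(
    layers: list[OmicsLayer],
    sheet: SampleSheet,
    reference: ClusterAssignment,
    result: CVResult,
    stable_features: list[str],
    clinical: tuple[str, ...] = ("gestational_age",),
) -> FittedClusterModel:
    """Refit the chosen elastic net on all complete-case samples using only
    the stable features."""
    if not stable_features:
        raise ContractError("no stable features to fit on")
    features = build_feature_matrix(layers, sheet, reference.sample_ids, clinical)
    x = features[stable_features].to_numpy()
    mean, sd = _standardize(x)
    clf = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=result.chosen_alpha,
        C=1.0 / (result.chosen_lambda * x.shape[0]),
        max_iter=10000,
        tol=1e-5,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit((x - mean) / sd, reference.labels)
    return FittedClusterModel(
        classifier=clf,
        stable_features=list(stable_features),
        means=pd.Series(mean, index=stable_features),
        sds=pd.Series(sd, index=stable_features),
        C=reference.C,
    )


def predict_incomplete_samples(
    model: FittedClusterModel,
    new_layers: list[OmicsLayer],
    new_sheet: SampleSheet,
    sample_ids: list[str],
    clinical: tuple[str, ...] = ("gestational_age",),
) -> ClusterAssignment:
    """Assign clusters to samples with incomplete omics.

    Stable features absent from a sample's available layers are mean-imputed
    (zero after training standardization); a sample with no stable feature at
    all is dropped with a warning.
    """
    z = pd.DataFrame(0.0, index=sample_ids, columns=model.stable_features)
    observed = pd.DataFrame(False, index=sample_ids, columns=model.stable_features)
    for layer in new_layers:
        have = [a for a in layer.analyte_ids if a in set(model.stable_features)]
        if not have:
            continue
        pos = {a: i for i, a in enumerate(layer.analyte_ids)}
        sub = layer.subset_analytes([pos[a] for a in have])
        for s in sample_ids:
            if s in set(sub.sample_ids):
                col = sub.values[:, sub.sample_ids.index(s)]
                z.loc[s, have] = (col - model.means[have].to_numpy()) / model.sds[
                    have
                ].to_numpy()
                observed.loc[s, have] = True
    for cov in clinical:
        names = [f for f in model.stable_features if f == f"clinical:{cov}"]
        for f in names:
            vals = new_sheet.frame.loc[sample_ids, cov].astype(float)
            z[f] = (vals - model.means[f]) / model.sds[f]
            observed[f] = True
    usable = observed.any(axis=1)
    dropped = [s for s in sample_ids if not usable[s]]
    if dropped:
        warnings.warn(f"samples missing every stable feature left unassigned: {dropped}")
    keep = [s for s in sample_ids if usable[s]]
    labels = model.classifier.predict(z.loc[keep].to_numpy())
    return ClusterAssignment(keep, labels, model.C, "propagated")


__all__ = [
    "match_cluster_labels",
    "brute_force_match",
    "multiclass_auc",
    "build_feature_matrix",
    "glmnet_lambda_path",
    "ElasticNetConfig",
    "CVResult",
    "select_stable_features",
    "full_data_clustering",
    "repeated_cv_elastic_net",
    "FittedClusterModel",
    "fit_final_model",
    "predict_incomplete_samples",
]
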