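"""Similarity network fusion, written from the fusion formulas up.

Per layer, a scaled Gaussian kernel on Euclidean distances between samples
gives an affinity graph; cross-diffusion between the per-layer graphs (global
transition kernels diffused through sparse k-nearest-neighbor kernels) yields
a single fused network; spectral clustering of that network defines the
sample clusters, with the cluster count chosen by the eigengap heuristic and
unseen samples assigned by label propagation with clamped training labels.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .core import (
    AffinityMatrix,
    ClusterAssignment,
    ContractError,
    OmicsLayer,
    SNFHyperparams,
)

EPS_FLOOR = 1e-12  # scale floor for coincident samples


def standard_normalize(layer: OmicsLayer) -> OmicsLayer:
    """Per-analyte z-scoring (mean 0, SD 1); zero-variance analytes map to zeros."""
    if layer.scale != "log":
        raise ContractError("standard_normalize requires a log-scale layer")
    v = layer.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (v - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return OmicsLayer(layer.datatype, layer.analyte_ids, layer.sample_ids, out, "log")


def _affinity_from_distance(d: np.ndarray, params: SNFHyperparams) -> np.ndarray:
    n = d.shape[0]
    if params.k >= n:
        raise ContractError(f"k = {params.k} must be < n_samples = {n}")
    # mean distance from each sample to its k nearest neighbors (self excluded)
    d_sorted = np.sort(d, axis=1)
    knn_mean = d_sorted[:, 1 : params.k + 1].mean(axis=1)
    eps = (knn_mean[:, None] + knn_mean[None, :] + d) / 3.0
    eps = np.maximum(eps, EPS_FLOOR)
    w = np.exp(-(d**2) / (params.mu * eps))
    return (w + w.T) / 2.0


def affinity_matrix(layer: OmicsLayer, params: SNFHyperparams) -> AffinityMatrix:
    """Scaled Gaussian kernel on Euclidean distances over (normalized) analytes:
    eps_ij = (mean kNN distance of i + mean kNN distance of j + d_ij) / 3 and
    W_ij = exp(-d_ij^2 / (mu * eps_ij))."""
    d = squareform(pdist(layer.values.T, metric="euclidean"))
    return AffinityMatrix(layer.sample_ids, _affinity_from_distance(d, params), params, "raw")


def _global_kernel(w: np.ndarray) -> np.ndarray:
    """P(i,j) = W(i,j) / (2 sum_{l != i} W(i,l)) off-diagonal, P(i,i) = 1/2."""
    off = w - np.diag(np.diag(w))
    rowsum = off.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    p = off / (2.0 * rowsum[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def _local_kernel(w: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized kNN graph: mass restricted to each sample's k nearest
    neighbors (by affinity), zero elsewhere."""
    n = w.shape[0]
    s = np.zeros_like(w)
    off = w - np.diag(np.diag(w))
    for i in range(n):
        nn = np.argsort(off[i])[::-1][:k]
        s[i, nn] = off[i, nn]
    rowsum = s.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    return s / rowsum[:, None]


def snf_fuse(affinities: list[AffinityMatrix], params: SNFHyperparams) -> AffinityMatrix:
    """Cross-diffusion of >= 2 affinity views into one fused network.

    Each view's global kernel is iteratively updated as
    P_v <- S_v . mean_{u != v}(P_u) . S_v^T for t iterations, renormalized and
    symmetrized each step; the fused affinity is the mean of the final kernels.
    """
    if len(affinities) < 2:
        raise ContractError(
            "snf_fuse needs >= 2 views; with a single view use its kernel directly"
        )
    ids = affinities[0].sample_ids
    for aff in affinities[1:]:
        if aff.sample_ids != ids:
            raise ContractError("all views must share an identical sample set/order")
    ps = [_global_kernel(a.W) for a in affinities]
    ss = [_local_kernel(a.W, params.k) for a in affinities]
    m = len(ps)
    for _ in range(params.t):
        new_ps = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p = ss[v] @ others @ ss[v].T
            # symmetrize, then renormalize: every P_v row sums to 1 exactly
            new_ps.append(_global_kernel((p + p.T) / 2.0))
        ps = new_ps
    fused = sum(ps) / m
    fused = (fused + fused.T) / 2.0
    return AffinityMatrix(ids, fused, params, "fused")


def _check_degrees(w: np.ndarray, sample_ids) -> np.ndarray:
    deg = w.sum(axis=1)
    dead = [sample_ids[i] for i in np.flatnonzero(deg <= 0)]
    if dead:
        raise ContractError(f"zero-degree sample(s) in affinity: {dead}")
    return deg


def spectral_cluster(aff: AffinityMatrix, C: int, seed: int = 0) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering (eigenvector k-means).

    Rows of the top-C eigenvector embedding of D^{-1/2} W D^{-1/2} are unit
    normalized and clustered by k-means with a fixed seed and 20 restarts;
    labels are renumbered by descending cluster size.
    """
    n = aff.n_samples
    if not (2 <= C < n):
        raise ContractError(f"need 2 <= C < n, got C={C}, n={n}")
    w = aff.W
    deg = _check_degrees(w, aff.sample_ids)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    l_sym = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    vals, vecs = scipy.linalg.eigh(l_sym, subset_by_index=(n - C, n - 1))
    # largest eigenvalues of the normalized affinity = smallest of I - L_sym
    emb = vecs[:, ::-1]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=C, n_init=20, random_state=seed % (2**31))
    raw = km.fit_predict(emb)
    # renumber by descending cluster size, ties by first occurrence
    sizes = np.bincount(raw, minlength=C)
    order = sorted(range(C), key=lambda c: (-sizes[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[r] for r in raw])
    return ClusterAssignment(aff.sample_ids, labels, C, "spectral")


def eigengap_select(aff: AffinityMatrix, c_min: int = 2, c_max: int = 10) -> int:
    """Cluster count with the largest gap between consecutive ascending
    eigenvalues of the random-walk Laplacian I - D^{-1} W; ties go to the
    smallest C."""
    n = aff.n_samples
    if n <= c_max:
        raise ContractError(f"need n > c_max (n={n}, c_max={c_max})")
    w = aff.W
    deg = _check_degrees(w, aff.sample_ids)
    # eigenvalues of I - D^{-1}W == generalized eigenvalues of (D - W, D)
    lap = np.diag(deg) - w
    vals = scipy.linalg.eigh(lap, np.diag(deg), eigvals_only=True)
    vals = np.sort(vals)
    gaps = vals[c_min : c_max + 1] - vals[c_min - 1 : c_max]  # gap at C = lam_{C+1}-lam_C
    best = int(np.argmax(gaps))  # argmax returns the first (smallest C) on ties
    return c_min + best


def fuse_layers(
    layers: list[OmicsLayer], params: SNFHyperparams, normalize: bool = True
) -> AffinityMatrix:
    """Convenience: z-score each layer, build per-layer affinities, fuse."""
    if normalize:
        layers = [standard_normalize(l) for l in layers]
    affs = [affinity_matrix(l, params) for l in layers]
    if len(affs) == 1:
        w = _global_kernel(affs[0].W)
        w = (w + w.T) / 2.0
        return AffinityMatrix(affs[0].sample_ids, w, params, "fused")
    return snf_fuse(affs, params)


def propagate_labels(
    train_layers: list[OmicsLayer],
    test_layers: list[OmicsLayer],
    train_assignment: ClusterAssignment,
    params: SNFHyperparams,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ClusterAssignment:
    """Semi-supervised label propagation over the fused train+test network.

    One-hot training labels are diffused through the row-normalized fused
    affinity, with training rows re-clamped each step, until the update
    changes by < tol; test labels are the row argmax. Training labels are
    returned unchanged.
    """
    if train_assignment.sample_ids != train_layers[0].sample_ids:
        raise ContractError("train assignment must cover the training layers' samples")
    combined = []
    for tr, te in zip(train_layers, test_layers):
        if tr.analyte_ids != te.analyte_ids:
            raise ContractError("train and test layers must share analytes")
        combined.append(
            OmicsLayer(
                tr.datatype,
                tr.analyte_ids,
                tr.sample_ids + te.sample_ids,
                np.hstack([tr.values, te.values]),
                tr.scale,
            )
        )
    fused = fuse_layers(combined, params)
    n_train = train_layers[0].n_samples
    n_total = fused.n_samples
    C = train_assignment.C
    p = fused.W / fused.W.sum(axis=1, keepdims=True)
    y = np.zeros((n_total, C))
    clamp = np.zeros((n_train, C))
    clamp[np.arange(n_train), train_assignment.labels - 1] = 1.0
    y[:n_train] = clamp
    converged = False
    for _ in range(max_iter):
        y_new = p @ y
        y_new[:n_train] = clamp
        if np.max(np.abs(y_new - y)) < tol:
            y = y_new
            converged = True
            break
        y = y_new
    if not converged:
        warnings.warn("label propagation did not converge; returning best iterate")
    test_labels = np.argmax(y[n_train:], axis=1) + 1
    all_labels = np.concatenate([train_assignment.labels, test_labels])
    return ClusterAssignment(
        train_assignment.sample_ids + test_layers[0].sample_ids, all_labels, C, "propagated"
    )


__all__ = [
    "standard_normalize",
    "affinity_matrix",
    "snf_fuse",
    "spectral_cluster",
    "eigengap_select",
    "fuse_layers",
    "propagate_labels",
]
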