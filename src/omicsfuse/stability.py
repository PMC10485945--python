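"""Hyperparameter selection by clustering stability.

For every (mu, k) grid cell, the full data set is fused and clustered once;
the same fusion + clustering is then repeated on random subsamples (default
50 draws of 80% of the samples, without replacement) and each subsample
clustering is scored against the full-data clustering restricted to the
subsample using adjusted mutual information (AMI). The cell with the highest
mean AMI — the most stable clustering — wins.

AMI is implemented with the exact hypergeometric permutation-null expectation
of mutual information and the arithmetic-mean-of-entropies normalizer:
AMI = (MI - E[MI]) / (mean(H(a), H(b)) - E[MI]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import ContractError, OmicsLayer, SNFHyperparams, derive_int_seed, derive_rng
from .snf import eigengap_select, fuse_layers, spectral_cluster


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def mutual_information(a, b) -> float:
    """MI (nats) between two label vectors, from the contingency table."""
    t = _contingency(np.asarray(a), np.asarray(b))
    n = t.sum()
    nz = t > 0
    pij = t[nz] / n
    pi = (t.sum(axis=1) / n)[np.nonzero(nz)[0]]
    pj = (t.sum(axis=0) / n)[np.nonzero(nz)[1]]
    return float(np.sum(pij * np.log(pij / (pi * pj))))


def entropy(labels) -> float:
    counts = np.bincount(np.unique(labels, return_inverse=True)[1])
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def expected_mutual_information(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Exact E[MI] under the permutation (hypergeometric) null for fixed
    marginals."""
    a = np.asarray(row_sums, dtype=np.int64)
    b = np.asarray(col_sums, dtype=np.int64)
    n = int(a.sum())
    if n != int(b.sum()):
        raise ContractError("marginals must share a total")
    gln_a = gammaln(a + 1)
    gln_b = gammaln(b + 1)
    gln_na = gammaln(n - a + 1)
    gln_nb = gammaln(n - b + 1)
    gln_n = gammaln(n + 1)
    emi = 0.0
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            term1 = (nij / n) * np.log(n * nij / (ai * bj))
            log_pmf = (
                gln_a[i]
                + gln_b[j]
                + gln_na[i]
                + gln_nb[j]
                - gln_n
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float(np.sum(term1 * np.exp(log_pmf)))
    return emi


def adjusted_mutual_information(a, b) -> float:
    """AMI with exact hypergeometric E[MI] and arithmetic-mean normalizer.

    Symmetric; <= 1; equals 1 iff the partitions are identical up to
    relabeling (including the degenerate both-single-cluster case).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ContractError("label vectors must be 1-D with equal nonzero length")
    t = _contingency(a, b)
    if t.shape == (1, 1):
        return 1.0  # both partitions single-cluster
    mi = mutual_information(a, b)
    emi = expected_mutual_information(t.sum(axis=1), t.sum(axis=0))
    normalizer = 0.5 * (entropy(a) + entropy(b))
    # sign-preserving eps floors: a perfect match whose null expectation
    # equals the maximum (all-singleton partitions) resolves to eps/eps = 1
    eps = np.finfo("float64").eps
    denom = normalizer - emi
    denom = min(denom, -eps) if denom < 0 else max(denom, eps)
    numer = mi - emi
    numer = min(numer, -eps) if numer < 0 else max(numer, eps)
    return float(numer / denom)


@dataclass
class StabilityConfig:
    mu_grid: list[float] = field(default_factory=lambda: [0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    k_grid: list[int] = field(default_factory=lambda: [10, 15, 20, 25, 30])
    n_subsamples: int = 50
    subsample_fraction: float = 0.8
    t: int = 20
    c_min: int = 2
    c_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_grid or not self.k_grid:
            raise ContractError("hyperparameter grids must be nonempty")
        if not (0.0 < self.subsample_fraction < 1.0):
            raise ContractError("subsample_fraction must lie in (0,1)")
        if self.n_subsamples < 1:
            raise ContractError("n_subsamples must be positive")


@dataclass
class StabilityResult:
    table: pd.DataFrame  # columns: mu, k, C, mean_ami, sd_ami, n_subsamples
    selected: SNFHyperparams
    per_cell_ami: dict[tuple[float, int], np.ndarray]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "selected": {"mu": self.selected.mu, "k": self.selected.k, "t": self.selected.t},
            "table": self.table.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def stability_grid_search(
    layers: list[OmicsLayer], config: StabilityConfig
) -> StabilityResult:
    """Grid search over (mu, k) scored by subsample-vs-full AMI.

    Each cell derives its own RNG stream from (seed, mu, k), so cells are
    individually reproducible and the whole search is deterministic given the
    seed. Ties in mean AMI go to the smaller k, then the smaller mu.
    """
    ids = layers[0].sample_ids
    for l in layers[1:]:
        if l.sample_ids != ids:
            raise ContractError("layers must share a common sample set/order")
    n = len(ids)
    n_sub = int(np.ceil(config.subsample_fraction * n))
    rows = []
    per_cell: dict[tuple[float, int], np.ndarray] = {}
    for mu in config.mu_grid:
        for k in config.k_grid:
            if k >= n_sub:
                warnings.warn(f"skipping grid cell (mu={mu}, k={k}): k >= subsample size {n_sub}")
                continue
            params = SNFHyperparams(mu=mu, k=k, t=config.t)
            full_fused = fuse_layers(layers, params)
            C = eigengap_select(full_fused, config.c_min, min(config.c_max, n - 1))
            full_labels = spectral_cluster(
                full_fused, C, derive_int_seed(config.seed, "full", mu, k)
            )
            rng = derive_rng(config.seed, "subsample", mu, k)
            amis = np.empty(config.n_subsamples)
            for s in range(config.n_subsamples):
                idx = np.sort(rng.choice(n, size=n_sub, replace=False))
                sub_ids = [ids[i] for i in idx]
                sub_layers = [l.subset_samples(sub_ids) for l in layers]
                sub_fused = fuse_layers(sub_layers, params)
                sub_labels = spectral_cluster(
                    sub_fused, C, derive_int_seed(config.seed, "sub", mu, k, s)
                )
                ref = full_labels.labels[idx]
                amis[s] = adjusted_mutual_information(sub_labels.labels, ref)
            per_cell[(mu, k)] = amis
            rows.append(
                {
                    "mu": mu,
                    "k": k,
                    "C": C,
                    "mean_ami": float(amis.mean()),
                    "sd_ami": float(amis.std(ddof=1)) if len(amis) > 1 else 0.0,
                    "n_subsamples": config.n_subsamples,
                }
            )
    if not rows:
        raise ContractError("every grid cell was skipped; grids incompatible with n")
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["mean_ami", "k", "mu"], ascending=[False, True, True], kind="mergesort"
    ).iloc[0]
    selected = SNFHyperparams(mu=float(best["mu"]), k=int(best["k"]), t=config.t)
    return StabilityResult(table=table, selected=selected, per_cell_ami=per_cell)


__all__ = [
    "mutual_information",
    "entropy",
    "expected_mutual_information",
    "adjusted_mutual_information",
    "StabilityConfig",
    "StabilityResult",
    "stability_grid_search",
]
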