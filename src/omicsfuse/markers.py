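"""One-vs-rest AUROC ranking of analytes as cluster markers.

The AUROC of an analyte for a cluster is the probability that a randomly
chosen in-cluster sample has a higher value than a randomly chosen
out-of-cluster sample (Mann-Whitney identity, midrank tie handling). The top
analytes per (cluster, datatype) define the molecular indicators of each
cluster; only up-regulation is ranked by default since markers are read as
uniquely elevated in their cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ClusterAssignment, ContractError, OmicsLayer


def auroc(values, is_positive) -> float:
    """Mann-Whitney AUROC: (#(pos > neg) + 0.5 #ties) / (n_pos * n_neg)."""
    values = np.asarray(values, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if values.shape != is_positive.shape:
        raise ContractError("values and is_positive must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be nonempty")
    ranks = rankdata(values)  # midranks
    u = ranks[is_positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auroc_rows(values: np.ndarray, is_positive: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for an analyte x sample matrix against one mask."""
    n_pos = int(is_positive.sum())
    n_neg = values.shape[1] - n_pos
    ranks = rankdata(values, axis=1)
    u = ranks[:, is_positive].sum(axis=1) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass
class MarkerTable:
    frame: pd.DataFrame  # analyte_id, datatype, cluster, auroc, rank

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def top(self, cluster: int, datatype: str) -> pd.DataFrame:
        f = self.frame
        return f[(f["cluster"] == cluster) & (f["datatype"] == datatype)]


def rank_markers(
    layers: list[OmicsLayer],
    assignment: ClusterAssignment,
    top_n: int = 10,
    direction: str = "up",
) -> MarkerTable:
    """Top one-vs-rest markers per (cluster, datatype).

    direction='up' ranks by AUROC (higher in cluster); 'both' additionally
    ranks down-regulated markers by 1 - AUROC in a separate 'down' table
    column. Ties break by analyte ID; ranks are contiguous from 1.
    """
    if direction not in ("up", "both"):
        raise ContractError("direction must be 'up' or 'both'")
    label_of = dict(zip(assignment.sample_ids, assignment.labels))
    rows = []
    for layer in layers:
        missing = [s for s in layer.sample_ids if s not in label_of]
        if missing:
            raise ContractError(f"assignment does not cover samples: {missing[:5]}")
        labels = np.array([label_of[s] for s in layer.sample_ids])
        for cluster in range(1, assignment.C + 1):
            mask = labels == cluster
            if mask.sum() < 2:
                warnings.warn(f"cluster {cluster} has < 2 samples in {layer.datatype}; skipped")
                continue
            if mask.all():
                warnings.warn(f"cluster {cluster} covers all samples in {layer.datatype}; skipped")
                continue
            scores = _auroc_rows(layer.values, mask)
            directions = [("up", scores)]
            if direction == "both":
                directions.append(("down", 1.0 - scores))
            for tag, sc in directions:
                order = sorted(
                    range(layer.n_analytes), key=lambda i: (-sc[i], layer.analyte_ids[i])
                )[: min(top_n, layer.n_analytes)]
                for rank, i in enumerate(order, start=1):
                    rows.append(
                        {
                            "analyte_id": layer.analyte_ids[i],
                            "datatype": layer.datatype,
                            "cluster": cluster,
                            "direction": tag,
                            "auroc": float(scores[i]),
                            "rank": rank,
                        }
                    )
    return MarkerTable(pd.DataFrame(rows))


def marker_expression_matrix(
    layers: list[OmicsLayer], assignment: ClusterAssignment, table: MarkerTable
) -> pd.DataFrame:
    """Heatmap-ready z-scored expression of the tabled markers, with samples
    ordered by cluster (analyte x sample)."""
    order = np.argsort(assignment.labels, kind="mergesort")
    sample_order = [assignment.sample_ids[i] for i in order]
    blocks = []
    for layer in layers:
        wanted = table.frame[table.frame["datatype"] == layer.datatype]["analyte_id"].unique()
        idx = [layer.analyte_ids.index(a) for a in wanted if a in set(layer.analyte_ids)]
        if not idx:
            continue
        sub = layer.subset_analytes(idx).subset_samples(sample_order)
        v = sub.values
        sd = v.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (v - v.mean(axis=1, keepdims=True)) / sd
        blocks.append(pd.DataFrame(z, index=sub.analyte_ids, columns=sub.sample_ids))
    return pd.concat(blocks) if blocks else pd.DataFrame()


__all__ = ["auroc", "MarkerTable", "rank_markers", "marker_expression_matrix"]
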