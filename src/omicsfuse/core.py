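"""Shared data containers for the multi-omics fusion pipeline.

Four analyte-by-sample matrices (RNA counts, miRNA counts, protein log
abundances, metabolite abundances) plus a per-sample clinical sheet flow
through every stage, so their containers live here rather than in any one
stage module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DATATYPES = ("rna", "mirna", "protein", "metabolite")
COUNT_DATATYPES = ("rna", "mirna")
TARGETED_DATATYPES = ("protein", "metabolite")

#: scale tags: ``count`` = nonnegative integer counts, ``linear`` = raw
#: positive abundances (pre log transform), ``log`` = log-scale values.
SCALES = ("count", "linear", "log")


class ContractError(ValueError):
    """An operation was called outside its documented contract."""


@dataclass
class OmicsLayer:
    """One analyte x sample matrix with datatype and value-scale metadata.

    ``values`` has shape (n_analytes, n_samples). ``lod_flags``, present only
    for the targeted layers (protein, metabolite), marks entries censored at
    the assay's limit of detection.
    """

    datatype: str
    analyte_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str
    lod_flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise ContractError(f"unknown datatype {self.datatype!r}")
        if self.scale not in SCALES:
            raise ContractError(f"unknown scale {self.scale!r}")
        self.analyte_ids = list(self.analyte_ids)
        self.sample_ids = list(self.sample_ids)
        if len(set(self.analyte_ids)) != len(self.analyte_ids):
            raise ContractError("duplicate analyte IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ContractError("duplicate sample IDs")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.analyte_ids), len(self.sample_ids)):
            raise ContractError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.analyte_ids)} analytes x {len(self.sample_ids)} samples"
            )
        if self.scale == "count":
            if self.values.size and (
                np.any(self.values < 0) or np.any(self.values != np.round(self.values))
            ):
                raise ContractError(
                    f"{self.datatype}: count-scale layer must hold nonnegative integers"
                )
        if self.lod_flags is not None:
            self.lod_flags = np.asarray(self.lod_flags, dtype=bool)
            if self.lod_flags.shape != self.values.shape:
                raise ContractError("lod_flags shape must match values shape")

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "OmicsLayer":
        return OmicsLayer(
            datatype=self.datatype,
            analyte_ids=list(self.analyte_ids),
            sample_ids=list(self.sample_ids),
            values=self.values.copy(),
            scale=self.scale,
            lod_flags=None if self.lod_flags is None else self.lod_flags.copy(),
        )

    def subset_analytes(self, keep_idx: Sequence[int]) -> "OmicsLayer":
        keep_idx = list(keep_idx)
        return OmicsLayer(
            datatype=self.datatype,
            analyte_ids=[self.analyte_ids[i] for i in keep_idx],
            sample_ids=list(self.sample_ids),
            values=self.values[keep_idx, :],
            scale=self.scale,
            lod_flags=None if self.lod_flags is None else self.lod_flags[keep_idx, :],
        )

    def subset_samples(self, keep_ids: Sequence[str]) -> "OmicsLayer":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep_ids]
        return OmicsLayer(
            datatype=self.datatype,
            analyte_ids=list(self.analyte_ids),
            sample_ids=list(keep_ids),
            values=self.values[:, idx],
            scale=self.scale,
            lod_flags=None if self.lod_flags is None else self.lod_flags[:, idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.analyte_ids, columns=self.sample_ids)


@dataclass
class SampleSheet:
    """Per-sample clinical metadata: batch, covariates, 6-level disease group,
    binary histopathology outcomes."""

    frame: pd.DataFrame  # indexed by sample_id
    outcome_columns: list[str] = field(default_factory=list)

    REQUIRED = ("batch", "disease_group", "gestational_age")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ContractError(f"sample sheet missing required column {col!r}")
        if self.frame.index.has_duplicates:
            raise ContractError("duplicate sample IDs in sample sheet")
        missing = [c for c in self.outcome_columns if c not in self.frame.columns]
        if missing:
            raise ContractError(f"outcome columns absent from sheet: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.frame.loc[list(sample_ids)].copy(), list(self.outcome_columns))


@dataclass
class SNFHyperparams:
    """Gaussian-kernel bandwidth multiplier mu, neighbor count k, fusion iterations t."""

    mu: float = 0.5
    k: int = 20
    t: int = 20

    def __post_init__(self) -> None:
        if not (self.mu > 0):
            raise ContractError("mu must be positive")
        if self.k < 1:
            raise ContractError("k must be a positive integer")
        if self.t < 1:
            raise ContractError("t must be a positive integer")


@dataclass
class AffinityMatrix:
    """Symmetric nonnegative sample-by-sample similarity."""

    sample_ids: list[str]
    W: np.ndarray
    hyperparams: SNFHyperparams
    kind: str = "raw"  # raw | fused

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sample_ids)
        if self.W.shape != (n, n):
            raise ContractError("affinity matrix must be square over sample_ids")
        if not np.all(np.isfinite(self.W)):
            raise ContractError("affinity matrix contains non-finite entries")
        if np.any(self.W < 0):
            raise ContractError("affinity matrix must be nonnegative")
        if n and np.max(np.abs(self.W - self.W.T)) > 1e-10:
            raise ContractError("affinity matrix must be symmetric within 1e-10")
        if self.kind not in ("raw", "fused"):
            raise ContractError(f"unknown affinity kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.W, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class ClusterAssignment:
    """Sample-to-cluster labels in {1..C} with provenance."""

    sample_ids: list[str]
    labels: np.ndarray
    C: int
    source: str = "spectral"  # spectral | propagated

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ContractError("labels must align with sample_ids")
        if self.source not in ("spectral", "propagated"):
            raise ContractError(f"unknown source {self.source!r}")
        if self.labels.size:
            if self.labels.min() < 1 or self.labels.max() > self.C:
                raise ContractError("labels must lie in {1..C}")
            if self.source == "spectral":
                present = np.unique(self.labels)
                if len(present) != self.C:
                    raise ContractError("spectral assignment must use every cluster")

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"sample_id": self.sample_ids, "cluster": self.labels, "source": self.source}
        ).to_csv(path, index=False)

    def restrict(self, sample_ids: Sequence[str]) -> "ClusterAssignment":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ClusterAssignment(list(sample_ids), self.labels[idx], self.C, self.source)


def derive_rng(seed: int, *context) -> np.random.Generator:
    """Deterministic per-context RNG stream derived from a global seed.

    The context tokens (strings, ints, floats) are hashed into a SeedSequence
    spawn key so every stage / grid cell / CV split gets an independent,
    individually reproducible stream.
    """
    key = []
    for token in context:
        if isinstance(token, float):
            token = np.float64(token).tobytes().hex()
        for byte in str(token).encode("utf8"):
            key.append(int(byte))
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=tuple(key))
    return np.random.default_rng(ss)


def derive_int_seed(seed: int, *context) -> int:
    """A plain integer seed (< 2**31) derived like :func:`derive_rng`."""
    key = []
    for token in context:
        if isinstance(token, float):
            token = np.float64(token).tobytes().hex()
        for byte in str(token).encode("utf8"):
            key.append(int(byte))
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


__all__ = [
    "DATATYPES",
    "COUNT_DATATYPES",
    "TARGETED_DATATYPES",
    "SCALES",
    "ContractError",
    "OmicsLayer",
    "SampleSheet",
    "SNFHyperparams",
    "AffinityMatrix",
    "ClusterAssignment",
    "derive_rng",
    "derive_int_seed",
    "replace",
]
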