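"""Synthetic multi-omics cohort generator with planted cluster structure.

Emulates a placental multi-omics study cohort: four omics layers (RNA and
miRNA negative-binomial counts, protein log-scale abundances, metabolite
positive abundances with detection limits), a clinical sample sheet with
biobank batch, gestational age correlated with cluster, a 6-level disease
group drawn from the true cluster through a confusion matrix, and binary
histopathology outcomes drawn from per-cluster logistic models. Ground-truth
cluster labels are kept apart from the sample sheet so the analysis pipeline
cannot consume them.

Counts follow a mean-dispersion negative binomial (variance = mu + mu^2/theta)
with log-normal library sizes and cluster-specific log-fold shifts on marker
analytes; targeted layers are Gaussian on the log scale with cluster shifts
on markers. Marker effect sizes are expressed in SD units of the analyte's
log-scale noise so that a 2-SD marker has a one-vs-rest AUROC near
Phi(2/sqrt(2)) ~ 0.92 regardless of layer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    COUNT_DATATYPES,
    DATATYPES,
    ContractError,
    OmicsLayer,
    SampleSheet,
)

DISEASE_LEVELS = ("control", "control_PT", "severe_PE", "FGR", "FGR_HDP", "sPTD")
OUTCOME_NAMES = ("MVM", "FVM", "AI", "CI")

# Cluster -> disease confusion emulating dominance of one syndrome per cluster
# (control-dominated, sPTD-dominated, PE/FGR+HDP, term-control + FGR).
DEFAULT_DISEASE_CONFUSION = np.array(
    [
        [0.62, 0.01, 0.08, 0.10, 0.01, 0.18],
        [0.10, 0.10, 0.08, 0.05, 0.02, 0.65],
        [0.03, 0.01, 0.45, 0.05, 0.38, 0.08],
        [0.40, 0.01, 0.09, 0.40, 0.03, 0.07],
    ]
)

# Per-outcome logits over the four clusters: one lesion strongly enriched in
# cluster 3, one enriched in 3 vs 2, two roughly flat.
DEFAULT_HISTOPATH_LOGITS = {
    "MVM": np.array([-0.50, -0.15, 1.50, -0.47]),
    "FVM": np.array([-1.10, -1.10, -1.10, -1.10]),
    "AI": np.array([-0.85, -0.85, -0.85, -0.85]),
    "CI": np.array([-2.20, -3.30, -1.10, -2.20]),
}

DEFAULT_GA_MEANS = (39.0, 33.0, 31.0, 38.0)  # weeks, per cluster


@dataclass
class LayerSpec:
    """Per-datatype generation parameters."""

    datatype: str
    n_analytes: int
    n_markers_per_cluster: int = 25
    marker_effect_size: float = 2.0  # SD units of log-scale noise
    dispersion: float = 8.0  # NB theta; count layers only
    lod_quantile: float = 0.1  # targeted layers only
    frac_poorly_detected: float = 0.0  # analytes censored past the 50% filter
    poorly_detected_quantile: float = 0.6

    def validate(self, n_clusters: int) -> None:
        if self.datatype not in DATATYPES:
            raise ContractError(f"unknown datatype {self.datatype!r}")
        if self.n_analytes < 1:
            raise ContractError(f"{self.datatype}: n_analytes must be positive")
        if self.n_markers_per_cluster * n_clusters > self.n_analytes:
            raise ContractError(
                f"{self.datatype}: n_markers_per_cluster x n_clusters exceeds n_analytes"
            )
        if self.marker_effect_size < 0:
            raise ContractError(f"{self.datatype}: marker_effect_size must be >= 0")
        if self.datatype in COUNT_DATATYPES and self.dispersion <= 0:
            raise ContractError(f"{self.datatype}: dispersion must be positive")
        for q in (self.lod_quantile, self.frac_poorly_detected, self.poorly_detected_quantile):
            if not (0.0 <= q <= 1.0):
                raise ContractError(f"{self.datatype}: rates/quantiles must lie in [0,1]")


def default_layer_specs() -> dict[str, LayerSpec]:
    return {
        "rna": LayerSpec("rna", n_analytes=1000, dispersion=8.0),
        "mirna": LayerSpec("mirna", n_analytes=300, dispersion=5.0),
        "protein": LayerSpec(
            "protein", n_analytes=453, lod_quantile=0.05, frac_poorly_detected=0.05
        ),
        "metabolite": LayerSpec(
            "metabolite", n_analytes=600, lod_quantile=0.10, frac_poorly_detected=0.08
        ),
    }


@dataclass
class CohortSpec:
    """Everything :func:`generate_cohort` needs; a pure function of this spec."""

    n_samples: int = 348
    n_clusters: int = 4
    cluster_proportions: Optional[np.ndarray] = None
    layers: dict[str, LayerSpec] = field(default_factory=default_layer_specs)
    n_batches: int = 2
    batch_effect_size: float = 0.5  # SD units on log scale
    ga_means: Optional[np.ndarray] = None  # gestational-age mean per cluster
    ga_sd: float = 2.0
    disease_confusion: Optional[np.ndarray] = None  # cluster x 6 row-stochastic
    histopath_logits: Optional[dict[str, np.ndarray]] = None
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {"rna": 0.09, "mirna": 0.09, "protein": 0.015, "metabolite": 0.02}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_clusters < 1:
            raise ContractError("n_samples and n_clusters must be positive")
        if self.cluster_proportions is None:
            if self.n_clusters == 4:
                self.cluster_proportions = np.array([0.38, 0.27, 0.22, 0.13])
            else:
                self.cluster_proportions = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_proportions = np.asarray(self.cluster_proportions, dtype=float)
        if self.cluster_proportions.shape != (self.n_clusters,):
            raise ContractError("cluster_proportions must have one entry per cluster")
        if np.any(self.cluster_proportions < 0) or abs(self.cluster_proportions.sum() - 1) > 1e-9:
            raise ContractError("cluster_proportions must be nonnegative and sum to 1")
        if self.ga_means is None:
            self.ga_means = (
                np.asarray(DEFAULT_GA_MEANS)
                if self.n_clusters == 4
                else np.linspace(31.0, 39.0, self.n_clusters)
            )
        self.ga_means = np.asarray(self.ga_means, dtype=float)
        if self.ga_means.shape != (self.n_clusters,):
            raise ContractError("ga_means must have one entry per cluster")
        if self.disease_confusion is None:
            if self.n_clusters == 4:
                self.disease_confusion = DEFAULT_DISEASE_CONFUSION.copy()
            else:
                # uniform fallback keeps rows stochastic for any cluster count
                self.disease_confusion = np.full(
                    (self.n_clusters, len(DISEASE_LEVELS)), 1.0 / len(DISEASE_LEVELS)
                )
        self.disease_confusion = np.asarray(self.disease_confusion, dtype=float)
        if self.disease_confusion.shape != (self.n_clusters, len(DISEASE_LEVELS)):
            raise ContractError("disease_confusion must be n_clusters x 6")
        if np.any(self.disease_confusion < 0) or np.any(
            np.abs(self.disease_confusion.sum(axis=1) - 1) > 1e-9
        ):
            raise ContractError("disease_confusion rows must be stochastic")
        if self.histopath_logits is None:
            if self.n_clusters == 4:
                self.histopath_logits = {k: v.copy() for k, v in DEFAULT_HISTOPATH_LOGITS.items()}
            else:
                self.histopath_logits = {
                    k: np.zeros(self.n_clusters) for k in OUTCOME_NAMES
                }
        for name, coefs in self.histopath_logits.items():
            coefs = np.asarray(coefs, dtype=float)
            if coefs.shape != (self.n_clusters,):
                raise ContractError(f"histopath logits for {name} must have one entry per cluster")
            self.histopath_logits[name] = coefs
        if self.n_batches < 1:
            raise ContractError("n_batches must be positive")
        for dt, rate in self.missingness_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ContractError(f"missingness rate for {dt} must lie in [0,1]")
        for dt, lspec in self.layers.items():
            if dt != lspec.datatype:
                raise ContractError(f"layer key {dt!r} != spec datatype {lspec.datatype!r}")
            lspec.validate(self.n_clusters)


@dataclass
class CohortBundle:
    """Generated layers + sample sheet + withheld ground truth.

    ``marker_owners`` (per datatype: analyte_id -> owning cluster in {1..C},
    0 for non-markers) is truth-side metadata like ``true_clusters``: it is
    never written into the analysis inputs and exists so tests can check the
    planted signal.
    """

    layers: dict[str, OmicsLayer]
    sheet: SampleSheet
    true_clusters: pd.Series  # indexed by sample_id, values in {1..C}
    marker_owners: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.sheet.sample_ids)
        for layer in self.layers.values():
            if not set(layer.sample_ids) <= universe:
                raise ContractError(
                    f"{layer.datatype}: layer samples outside the sample-sheet universe"
                )

    def complete_case_ids(self) -> list[str]:
        """Samples present in every layer, in sheet order."""
        have = set(self.sheet.sample_ids)
        for layer in self.layers.values():
            have &= set(layer.sample_ids)
        return [s for s in self.sheet.sample_ids if s in have]


LIBSIZE_LOG_SD = 0.3  # natural-log SD of library sizes


def _log2_sd_nb(mean: np.ndarray, theta: float) -> np.ndarray:
    """Delta-method SD of log2(count) for NB(mean, theta) including the
    library-size spread, so marker effect sizes are calibrated in units of the
    analyte's total log-scale SD (as for the Gaussian layers)."""
    return np.sqrt(
        1.0 / np.maximum(mean, 1e-9) + 1.0 / theta + LIBSIZE_LOG_SD**2
    ) / np.log(2.0)


def _marker_map(lspec: LayerSpec, n_clusters: int, rng: np.random.Generator) -> np.ndarray:
    """Return analyte -> cluster marker assignment (-1 = not a marker),
    disjoint across clusters."""
    owners = np.full(lspec.n_analytes, -1, dtype=int)
    chosen = rng.choice(
        lspec.n_analytes, size=lspec.n_markers_per_cluster * n_clusters, replace=False
    )
    for c in range(n_clusters):
        idx = chosen[c * lspec.n_markers_per_cluster : (c + 1) * lspec.n_markers_per_cluster]
        owners[idx] = c
    return owners


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a cohort; bit-identical for identical specs (including seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    C = spec.n_clusters
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    clusters = rng.choice(C, size=n, p=spec.cluster_proportions)  # 0-based
    batches = rng.integers(0, spec.n_batches, size=n)
    ga = spec.ga_means[clusters] + rng.normal(0.0, spec.ga_sd, size=n)
    disease_idx = np.array(
        [rng.choice(len(DISEASE_LEVELS), p=spec.disease_confusion[c]) for c in clusters]
    )
    sheet_cols = {
        "batch": [f"B{b + 1}" for b in batches],
        "disease_group": [DISEASE_LEVELS[i] for i in disease_idx],
        "gestational_age": np.round(ga, 3),
    }
    for name, coefs in spec.histopath_logits.items():
        p = 1.0 / (1.0 + np.exp(-coefs[clusters]))
        sheet_cols[name] = (rng.random(n) < p).astype(int)
    sheet = SampleSheet(
        pd.DataFrame(sheet_cols, index=pd.Index(sample_ids, name="sample_id")),
        outcome_columns=list(spec.histopath_logits.keys()),
    )
    truth = pd.Series(clusters + 1, index=pd.Index(sample_ids, name="sample_id"), name="true_cluster")

    layers: dict[str, OmicsLayer] = {}
    marker_owners: dict[str, pd.Series] = {}
    for dt in DATATYPES:
        if dt not in spec.layers:
            continue
        lspec = spec.layers[dt]
        owners = _marker_map(lspec, C, rng)
        ids = [f"{dt}_{i + 1:05d}" for i in range(lspec.n_analytes)]
        marker_owners[dt] = pd.Series(owners + 1, index=ids, name="owner_cluster")
        batch_shift = rng.normal(0.0, spec.batch_effect_size, size=(lspec.n_analytes, spec.n_batches))
        is_marker = owners >= 0
        marker_of_sample = (owners[:, None] == clusters[None, :])  # analyte x sample

        if dt in COUNT_DATATYPES:
            base = rng.uniform(-2.0, 9.0, size=lspec.n_analytes)
            # markers get solidly expressed baselines so count filters never
            # remove planted signal
            base[is_marker] = rng.uniform(5.0, 9.0, size=int(is_marker.sum()))
            sd_log2 = _log2_sd_nb(2.0 ** base, lspec.dispersion)
            log2_mu = (
                base[:, None]
                + batch_shift[:, batches]
                + lspec.marker_effect_size * sd_log2[:, None] * marker_of_sample
            )
            libsize = np.exp(rng.normal(0.0, LIBSIZE_LOG_SD, size=n))
            mu = (2.0 ** log2_mu) * libsize[None, :]
            theta = lspec.dispersion
            counts = rng.negative_binomial(theta, theta / (theta + mu))
            layers[dt] = OmicsLayer(dt, ids, sample_ids, counts.astype(float), "count")
        else:
            lo, hi = (2.0, 8.0) if dt == "protein" else (10.0, 20.0)
            base = rng.uniform(lo, hi, size=lspec.n_analytes)
            log_vals = (
                base[:, None]
                + batch_shift[:, batches]
                + lspec.marker_effect_size * marker_of_sample
                + rng.normal(0.0, 1.0, size=(lspec.n_analytes, n))
            )
            q = np.full(lspec.n_analytes, lspec.lod_quantile)
            n_poor = int(round(lspec.frac_poorly_detected * lspec.n_analytes))
            if n_poor:
                poor = rng.choice(
                    np.flatnonzero(~is_marker), size=min(n_poor, int((~is_marker).sum())),
                    replace=False,
                )
                q[poor] = lspec.poorly_detected_quantile
            if dt == "protein":
                values, scale = log_vals, "log"
            else:
                values, scale = 2.0 ** log_vals, "linear"
            thresh = np.array([np.quantile(values[a], q[a]) for a in range(lspec.n_analytes)])
            flags = values <= thresh[:, None]
            layers[dt] = OmicsLayer(dt, ids, sample_ids, values, scale, lod_flags=flags)

    return CohortBundle(
        layers=layers, sheet=sheet, true_clusters=truth, marker_owners=marker_owners
    )


def plant_missingness(bundle: CohortBundle, spec: CohortSpec) -> CohortBundle:
    """Independently drop samples from layers at per-datatype rates.

    Every sample keeps at least one layer (the lowest-rate layer is retained
    when a sample would otherwise lose all of them). Deterministic given
    spec.seed.
    """
    rates = {dt: spec.missingness_rates.get(dt, 0.0) for dt in bundle.layers}
    if rates and all(r >= 1.0 for r in rates.values()):
        raise ContractError("all missingness rates are 1: no sample would keep any layer")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed % (2**31), spawn_key=(77,)))
    sample_ids = bundle.sheet.sample_ids
    drop = {
        dt: rng.random(len(sample_ids)) < rates[dt] for dt in bundle.layers
    }
    fallback = min(rates, key=lambda dt: (rates[dt], dt)) if rates else None
    for i in range(len(sample_ids)):
        if bundle.layers and all(drop[dt][i] for dt in bundle.layers):
            drop[fallback][i] = False
    idx_of = {s: i for i, s in enumerate(sample_ids)}
    new_layers = {}
    for dt, layer in bundle.layers.items():
        keep = [s for s in layer.sample_ids if not drop[dt][idx_of[s]]]
        new_layers[dt] = layer.subset_samples(keep)
    return CohortBundle(new_layers, bundle.sheet, bundle.true_clusters, bundle.marker_owners)


# ---------------------------------------------------------------------------
# On-disk round trip: TSV per layer (analytes x samples), sample sheet CSV,
# ground-truth labels in a clearly named separate file.
# ---------------------------------------------------------------------------

LAYER_FILE = "{dt}.tsv"
LOD_FILE = "{dt}.lod.tsv"
SHEET_FILE = "samples.csv"
TRUTH_FILE = "TRUE_CLUSTERS.groundtruth.csv"


def write_cohort(bundle: CohortBundle, directory) -> list[str]:
    os.makedirs(directory, exist_ok=True)
    written = []
    try:
        for dt, layer in bundle.layers.items():
            df = layer.to_dataframe()
            if layer.scale == "count":
                df = df.astype(int)
            path = os.path.join(directory, LAYER_FILE.format(dt=dt))
            df.to_csv(path, sep="\t", index_label="analyte_id")
            written.append(path)
            if layer.lod_flags is not None:
                lpath = os.path.join(directory, LOD_FILE.format(dt=dt))
                pd.DataFrame(
                    layer.lod_flags.astype(int), index=layer.analyte_ids, columns=layer.sample_ids
                ).to_csv(lpath, sep="\t", index_label="analyte_id")
                written.append(lpath)
        spath = os.path.join(directory, SHEET_FILE)
        bundle.sheet.frame.to_csv(spath, index_label="sample_id")
        written.append(spath)
        tpath = os.path.join(directory, TRUTH_FILE)
        bundle.true_clusters.to_frame().to_csv(tpath, index_label="sample_id")
        written.append(tpath)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory!r}: {exc}") from exc
    return written


def read_layer(path, datatype: str, scale: str, lod_path=None) -> OmicsLayer:
    try:
        df = pd.read_csv(path, sep="\t", index_col="analyte_id")
    except OSError as exc:
        raise OSError(f"failed reading layer {datatype} from {path!r}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    if scale == "count" and values.size and np.any(values != np.round(values)):
        raise ContractError(f"{datatype}: count layer at {path!r} contains non-integer values")
    flags = None
    if lod_path is not None and os.path.exists(lod_path):
        flags = (
            pd.read_csv(lod_path, sep="\t", index_col="analyte_id")
            .to_numpy(dtype=float)
            .astype(bool)
        )
    return OmicsLayer(
        datatype, list(df.index.astype(str)), list(df.columns.astype(str)), values, scale, flags
    )


def read_cohort(directory, outcome_columns=None) -> CohortBundle:
    scales = {"rna": "count", "mirna": "count", "protein": "log", "metabolite": "linear"}
    layers = {}
    for dt in DATATYPES:
        path = os.path.join(directory, LAYER_FILE.format(dt=dt))
        if os.path.exists(path):
            layers[dt] = read_layer(
                path, dt, scales[dt], os.path.join(directory, LOD_FILE.format(dt=dt))
            )
    frame = pd.read_csv(os.path.join(directory, SHEET_FILE), index_col="sample_id")
    frame.index = frame.index.astype(str)
    if outcome_columns is None:
        outcome_columns = [c for c in OUTCOME_NAMES if c in frame.columns]
    sheet = SampleSheet(frame, outcome_columns=list(outcome_columns))
    tpath = os.path.join(directory, TRUTH_FILE)
    if os.path.exists(tpath):
        truth = pd.read_csv(tpath, index_col="sample_id")["true_cluster"]
        truth.index = truth.index.astype(str)
    else:
        truth = pd.Series(dtype=int)
    return CohortBundle(layers, sheet, truth)


# ---------------------------------------------------------------------------
# focused generators for calibration studies
# ---------------------------------------------------------------------------

def planted_feature_cohort(
    seed: int = 0,
    n: int = 200,
    effect: float = 2.0,
    n_informative: tuple[int, int] = (3, 2),
    n_decoys: tuple[int, int] = (100, 100),
):
    """Two log-scale layers with a handful of informative analytes among
    decoys, for classifier feature-recovery studies.

    A balanced 2-cluster structure shifts each informative analyte by `effect`
    noise-SD units in cluster 2; decoys are pure noise. Gestational age in the
    sheet is independent of cluster. Returns (layers, sheet, true_clusters).
    """
    rng = np.random.default_rng(seed)
    clusters = rng.permutation(np.array([1] * (n // 2) + [2] * (n - n // 2)))
    ids = [f"S{i:04d}" for i in range(n)]

    def make(dt, n_info, n_decoy):
        names = [f"{dt}_info_{i}" for i in range(n_info)] + [
            f"{dt}_decoy_{i}" for i in range(n_decoy)
        ]
        v = rng.normal(0.0, 1.0, size=(n_info + n_decoy, n))
        v[:n_info, :] += effect * (clusters == 2)[None, :]
        return OmicsLayer(dt, names, ids, v, "log")

    layers = [make("protein", n_informative[0], n_decoys[0]),
              make("metabolite", n_informative[1], n_decoys[1])]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "batch": ["B1"] * n,
                "disease_group": ["control"] * n,
                "gestational_age": rng.normal(30.0, 1.0, n),
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )
    return layers, sheet, clusters


def outcome_cohort(seed: int, n: int = 250, generator: str = "clusters", n_clusters: int = 4):
    """Sample sheet + cluster assignment with one binary outcome generated
    either from the cluster labels or from the disease labels, for BIC
    model-selection studies. Returns (sheet, ClusterAssignment)."""
    from .core import ClusterAssignment

    rng = np.random.default_rng(seed)
    clusters = rng.integers(1, n_clusters + 1, n)
    confusion = (
        DEFAULT_DISEASE_CONFUSION
        if n_clusters == 4
        else np.full((n_clusters, 6), 1.0 / 6)
    )
    disease = np.array(
        [DISEASE_LEVELS[rng.choice(6, p=confusion[c - 1])] for c in clusters]
    )
    if generator == "clusters":
        logits = np.resize(np.array([-1.5, -0.5, 1.5, 0.5]), n_clusters)[clusters - 1]
    elif generator == "disease":
        per_disease = dict(zip(DISEASE_LEVELS, [-1.5, -1.5, 1.5, 0.0, 1.5, -0.5]))
        logits = np.array([per_disease[d] for d in disease])
    else:
        raise ContractError(f"unknown outcome generator {generator!r}")
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    ids = [f"S{i}" for i in range(n)]
    sheet = SampleSheet(
        pd.DataFrame(
            {"batch": "B1", "disease_group": disease, "gestational_age": 30.0, "OUT": y},
            index=pd.Index(ids, name="sample_id"),
        ),
        outcome_columns=["OUT"],
    )
    return sheet, ClusterAssignment(ids, clusters, n_clusters, "spectral")


__all__ = [
    "DISEASE_LEVELS",
    "OUTCOME_NAMES",
    "planted_feature_cohort",
    "outcome_cohort",
    "LayerSpec",
    "CohortSpec",
    "CohortBundle",
    "default_layer_specs",
    "generate_cohort",
    "plant_missingness",
    "write_cohort",
    "read_cohort",
    "read_layer",
]
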