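import numpy as np
import pandas as pd
import pytest

import omicsfuse as of
from omicsfuse.core import OmicsLayer, SampleSheet
from omicsfuse.preprocess import preprocess_bundle

NO_MISSING = {"rna": 0.0, "mirna": 0.0, "protein": 0.0, "metabolite": 0.0}


def small_cohort_spec(n=120, effect=2.0, seed=0, missing=False, n_clusters=4):
    """A reduced cohort used across tests: smaller layers, same structure."""
    spec = of.CohortSpec(
        n_samples=n,
        n_clusters=n_clusters,
        seed=seed,
        missingness_rates=dict(of.CohortSpec().missingness_rates) if missing else dict(NO_MISSING),
        layers={
            "rna": of.LayerSpec("rna", n_analytes=400, n_markers_per_cluster=15),
            "mirna": of.LayerSpec("mirna", n_analytes=150, n_markers_per_cluster=10),
            "protein": of.LayerSpec(
                "protein", n_analytes=200, n_markers_per_cluster=10,
                lod_quantile=0.05, frac_poorly_detected=0.05,
            ),
            "metabolite": of.LayerSpec(
                "metabolite", n_analytes=250, n_markers_per_cluster=10,
                lod_quantile=0.10, frac_poorly_detected=0.08,
            ),
        },
    )
    for lspec in spec.layers.values():
        lspec.marker_effect_size = effect
    return spec


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated 4-cluster cohort, no missingness."""
    spec = small_cohort_spec(n=150, effect=2.5, seed=42)
    return spec, of.generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_layers(separated_cohort):
    spec, bundle = separated_cohort
    layers, report = preprocess_bundle(
        bundle.layers, bundle.sheet, preserve=["disease_group", "gestational_age"]
    )
    return list(layers.values()), bundle, report


def gaussian_layer(values, datatype="protein", scale="log", prefix="a", sample_prefix="s"):
    """Wrap a raw matrix as an OmicsLayer with generated IDs."""
    values = np.asarray(values, dtype=float)
    return OmicsLayer(
        datatype,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        values,
        scale,
    )


def trivial_sheet(sample_ids, batch=None, **extra):
    n = len(sample_ids)
    cols = {
        "batch": batch if batch is not None else ["B1"] * n,
        "disease_group": ["control"] * n,
        "gestational_age": np.linspace(30, 40, n),
    }
    cols.update(extra)
    return SampleSheet(pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id")))
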