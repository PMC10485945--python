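"""End-to-end orchestration: simulate/ingest -> preprocess -> stability search
-> fuse + cluster -> markers -> cross-validated prediction -> BIC comparison.

Stages communicate through files in the output directory so any stage can be
re-run individually; a run manifest (resolved config, seed, versions, config
hash) makes a run reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ContractError, SNFHyperparams, derive_int_seed
from .model_comparison import compare_models
from .markers import rank_markers, marker_expression_matrix
from .predict import (
    ElasticNetConfig,
    fit_final_model,
    predict_incomplete_samples,
    repeated_cv_elastic_net,
    select_stable_features,
)
from .preprocess import preprocess_bundle
from .snf import eigengap_select, fuse_layers, spectral_cluster
from .stability import StabilityConfig, stability_grid_search
from .synthetic import (
    CohortSpec,
    LayerSpec,
    default_layer_specs,
    generate_cohort,
    plant_missingness,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger("omicsfuse")


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration.

    Exactly one of `input_dir` (read an on-disk cohort) or `synthetic`
    (generate one) must be set.
    """

    seed: int = 0
    input_dir: Optional[str] = None
    synthetic: Optional[CohortSpec] = None
    preprocess: dict = field(
        default_factory=lambda: {
            "exclusion_list": [],
            "preserve": ["disease_group", "gestational_age"],
            "variance_quantile": 0.25,
            "pca_outlier_sd": 4.0,
        }
    )
    stability: Optional[StabilityConfig] = None
    snf: Optional[SNFHyperparams] = None  # overrides stability selection
    elastic_net: Optional[ElasticNetConfig] = None
    outcomes: Optional[list[str]] = None
    n_clusters: Optional[int] = None  # overrides eigengap
    run_cv: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ContractError("exactly one of input_dir / synthetic must be given")
        if self.snf is None and self.stability is None:
            self.stability = StabilityConfig(seed=self.seed)
        if self.elastic_net is None:
            self.elastic_net = ElasticNetConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "input_dir": self.input_dir,
            "synthetic": None,
            "preprocess": dict(self.preprocess),
            "stability": None if self.stability is None else asdict(self.stability),
            "snf": None if self.snf is None else asdict(self.snf),
            "elastic_net": asdict(self.elastic_net),
            "outcomes": self.outcomes,
            "n_clusters": self.n_clusters,
            "run_cv": self.run_cv,
            "log_level": self.log_level,
        }
        if self.synthetic is not None:
            s = self.synthetic
            d["synthetic"] = {
                "n_samples": s.n_samples,
                "n_clusters": s.n_clusters,
                "cluster_proportions": list(map(float, s.cluster_proportions)),
                "layers": {k: asdict(v) for k, v in s.layers.items()},
                "n_batches": s.n_batches,
                "batch_effect_size": s.batch_effect_size,
                "ga_means": list(map(float, s.ga_means)),
                "ga_sd": s.ga_sd,
                "disease_confusion": [list(map(float, r)) for r in s.disease_confusion],
                "histopath_logits": {
                    k: list(map(float, v)) for k, v in s.histopath_logits.items()
                },
                "missingness_rates": dict(s.missingness_rates),
                "seed": s.seed,
            }
        return d


_TOP_KEYS = {
    "seed", "input_dir", "synthetic", "preprocess", "stability", "snf",
    "elastic_net", "outcomes", "n_clusters", "run_cv", "log_level",
}


def config_from_dict(raw: dict) -> PipelineConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ContractError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("seed", "input_dir", "outcomes", "n_clusters", "run_cv", "log_level"):
        if key in raw:
            kwargs[key] = raw[key]
    if "preprocess" in raw:
        base = PipelineConfig.__dataclass_fields__["preprocess"].default_factory()
        bad = set(raw["preprocess"]) - set(base)
        if bad:
            raise ContractError(f"unknown preprocess keys: {sorted(bad)}")
        base.update(raw["preprocess"])
        kwargs["preprocess"] = base
    if raw.get("synthetic") is not None:
        s = dict(raw["synthetic"])
        layer_specs = default_layer_specs()
        if "layers" in s:
            specs = {}
            for dt, lraw in s.pop("layers").items():
                lraw = dict(lraw)
                lraw.setdefault("datatype", dt)
                try:
                    specs[dt] = LayerSpec(**lraw)
                except TypeError as exc:
                    raise ContractError(f"invalid layer spec for {dt!r}: {exc}") from exc
            layer_specs = specs
        for arr_key in ("cluster_proportions", "ga_means"):
            if s.get(arr_key) is not None:
                s[arr_key] = np.asarray(s[arr_key], dtype=float)
        if s.get("disease_confusion") is not None:
            s["disease_confusion"] = np.asarray(s["disease_confusion"], dtype=float)
        if s.get("histopath_logits") is not None:
            s["histopath_logits"] = {
                k: np.asarray(v, dtype=float) for k, v in s["histopath_logits"].items()
            }
        try:
            kwargs["synthetic"] = CohortSpec(layers=layer_specs, **s)
        except TypeError as exc:
            raise ContractError(f"invalid synthetic spec: {exc}") from exc
    if raw.get("stability") is not None:
        try:
            kwargs["stability"] = StabilityConfig(**raw["stability"])
        except TypeError as exc:
            raise ContractError(f"invalid stability config: {exc}") from exc
    if raw.get("snf") is not None:
        try:
            kwargs["snf"] = SNFHyperparams(**raw["snf"])
        except TypeError as exc:
            raise ContractError(f"invalid snf params: {exc}") from exc
    if raw.get("elastic_net") is not None:
        try:
            kwargs["elastic_net"] = ElasticNetConfig(**raw["elastic_net"])
        except TypeError as exc:
            raise ContractError(f"invalid elastic_net config: {exc}") from exc
    return PipelineConfig(**kwargs)


def validate_config(path) -> PipelineConfig:
    """Parse, default and validate a YAML config file; unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ContractError("config must be a mapping")
    return config_from_dict(raw)


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in order, writing each stage's outputs to `outdir`.

    Deterministic: identical config -> identical outputs. On a stage failure,
    partial outputs are retained next to a FAILED marker naming the stage.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(outdir, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        if config.synthetic is not None:
            logger.info("simulating cohort (n=%d)", config.synthetic.n_samples)
            bundle = plant_missingness(generate_cohort(config.synthetic), config.synthetic)
            write_cohort(bundle, os.path.join(outdir, "cohort"))
        else:
            bundle = read_cohort(config.input_dir)
        results["bundle"] = bundle

        stage = "preprocess"
        complete = bundle.complete_case_ids()
        layers_cc = {dt: l.subset_samples(complete) for dt, l in bundle.layers.items()}
        processed, report = preprocess_bundle(
            layers_cc,
            bundle.sheet,
            exclusion_list=config.preprocess["exclusion_list"],
            preserve=config.preprocess["preserve"],
            variance_quantile=config.preprocess["variance_quantile"],
            pca_outlier_sd=config.preprocess["pca_outlier_sd"],
        )
        report.to_json(os.path.join(outdir, "preprocess_report.json"))
        layer_list = list(processed.values())
        results["layers"] = processed

        stage = "stability"
        if config.snf is not None:
            params = config.snf
        else:
            st = stability_grid_search(layer_list, config.stability)
            st.to_csv(os.path.join(outdir, "stability.csv"))
            st.to_json(os.path.join(outdir, "stability.json"))
            params = st.selected
            results["stability"] = st
        results["snf_params"] = params

        stage = "cluster"
        fused = fuse_layers(layer_list, params)
        fused.to_tsv(os.path.join(outdir, "fused_affinity.tsv"))
        C = config.n_clusters or eigengap_select(fused, 2, min(10, fused.n_samples - 1))
        assignment = spectral_cluster(fused, C, derive_int_seed(config.seed, "cluster"))
        assignment.to_csv(os.path.join(outdir, "clusters.csv"))
        results["fused"] = fused
        results["clusters"] = assignment

        stage = "markers"
        table = rank_markers(layer_list, assignment)
        table.to_csv(os.path.join(outdir, "markers.csv"))
        marker_expression_matrix(layer_list, assignment, table).to_csv(
            os.path.join(outdir, "marker_expression.csv")
        )
        results["markers"] = table

        if config.run_cv:
            stage = "predict-cv"
            cv = repeated_cv_elastic_net(
                layer_list,
                bundle.sheet,
                params,
                config.elastic_net,
                reference=assignment,
                variance_quantile=config.preprocess["variance_quantile"],
            )
            cv.to_json(os.path.join(outdir, "cv_result.json"))
            cv.selection_frequency_csv(os.path.join(outdir, "selection_frequency.csv"))
            results["cv"] = cv
            stable = select_stable_features(cv, config.elastic_net.selection_threshold)
            results["stable_features"] = stable
            incomplete = [s for s in bundle.sheet.sample_ids if s not in set(complete)]
            if stable and incomplete:
                model = fit_final_model(layer_list, bundle.sheet, assignment, cv, stable)
                preds = predict_incomplete_samples(
                    model,
                    [l for l in bundle.layers.values()],
                    bundle.sheet,
                    incomplete,
                )
                preds.to_csv(os.path.join(outdir, "incomplete_predictions.csv"))
                results["incomplete_predictions"] = preds

        stage = "compare-bic"
        evidence = compare_models(
            bundle.sheet.subset(assignment.sample_ids), assignment, config.outcomes
        )
        evidence.to_csv(os.path.join(outdir, "evidence.csv"))
        evidence.to_json(os.path.join(outdir, "evidence.json"))
        results["evidence"] = evidence

        stage = "manifest"
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "versions": {
                "omicsfuse": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write(f"stage: {stage}\nerror: {exc}\n")
        raise ContractError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results


def config_from_manifest(path) -> PipelineConfig:
    """Reconstruct the config of a finished run from its manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    return config_from_dict(manifest["config"])


__all__ = [
    "PipelineConfig",
    "config_from_dict",
    "validate_config",
    "run_pipeline",
    "config_from_manifest",
]
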