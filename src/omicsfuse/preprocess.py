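"""Per-datatype filtering, transformation, outlier removal, batch adjustment
and variance filtering that turn raw omics layers into fusion-ready matrices.

All count thresholds are applied with strict inequality exactly as stated
(total < 500, zero fraction > 0.80, mean < 10, below-LOD fraction > 0.5), so
boundary analytes survive. The variance-stabilizing step is size-factor
(median-of-ratios) normalization followed by log2(x+1); downstream fusion
consumes per-analyte z-scores, which absorb monotone differences from a
dispersion-fitted transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import (
    COUNT_DATATYPES,
    TARGETED_DATATYPES,
    ContractError,
    OmicsLayer,
    SampleSheet,
)


@dataclass
class PreprocessReport:
    """Per-step record of removed analytes / samples with reasons."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, *, removed_analytes=(), removed_samples=(), params=None) -> None:
        self.steps.append(
            {
                "step": step,
                "removed_analytes": list(removed_analytes),
                "removed_samples": list(removed_samples),
                "params": dict(params or {}),
            }
        )

    def removed_analytes(self) -> list[str]:
        return [a for s in self.steps for a in s["removed_analytes"]]

    def to_json(self, path=None) -> str:
        text = json.dumps({"steps": self.steps}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_low_expression(
    layer: OmicsLayer, exclusion_list=()
) -> tuple[OmicsLayer, PreprocessReport]:
    """Count filters: RNA drops analytes with total < 500, zero fraction > 0.80
    or ID on the exclusion list (e.g. Y-chromosome genes, XIST, TSIX); miRNA
    drops analytes with mean count < 10. Strict inequalities; order preserved."""
    if layer.scale != "count" or layer.datatype not in COUNT_DATATYPES:
        raise ContractError("filter_low_expression requires a count layer (rna or mirna)")
    excl = set(exclusion_list)
    v = layer.values
    report = PreprocessReport()
    if layer.datatype == "rna":
        total = v.sum(axis=1)
        zero_frac = (v == 0).mean(axis=1) if v.shape[1] else np.zeros(v.shape[0])
        drop = (total < 500) | (zero_frac > 0.80)
        drop |= np.array([a in excl for a in layer.analyte_ids])
        params = {"min_total": 500, "max_zero_fraction": 0.80, "n_excluded_ids": len(excl)}
    else:
        mean = v.mean(axis=1) if v.shape[1] else np.zeros(v.shape[0])
        drop = mean < 10
        params = {"min_mean": 10}
    keep_idx = np.flatnonzero(~drop)
    report.add(
        f"filter_low_expression[{layer.datatype}]",
        removed_analytes=[layer.analyte_ids[i] for i in np.flatnonzero(drop)],
        params=params,
    )
    return layer.subset_analytes(keep_idx), report


def normalize_transform(layer: OmicsLayer) -> OmicsLayer:
    """Median-of-ratios size factors, then log2(count / size_factor + 1).

    The reference set is the analytes with all-positive counts; if none exist,
    size factors fall back to total-count ratios.
    """
    if layer.scale != "count":
        raise ContractError("normalize_transform requires a count layer")
    v = layer.values
    totals = v.sum(axis=0)
    zero_samples = [s for s, t in zip(layer.sample_ids, totals) if t == 0]
    if zero_samples:
        raise ContractError(f"size factor undefined for all-zero sample(s): {zero_samples}")
    all_pos = np.all(v > 0, axis=1)
    if np.any(all_pos):
        logs = np.log(v[all_pos, :])
        ref = logs.mean(axis=1)  # log geometric mean per analyte
        sf = np.exp(np.median(logs - ref[:, None], axis=0))
    else:
        sf = totals / np.exp(np.mean(np.log(totals)))
    out = np.log2(v / sf[None, :] + 1.0)
    return OmicsLayer(layer.datatype, layer.analyte_ids, layer.sample_ids, out, "log")


def log_transform(layer: OmicsLayer) -> OmicsLayer:
    """log2 of a positive linear-scale layer (metabolites)."""
    if layer.scale != "linear":
        raise ContractError("log_transform requires a linear-scale layer")
    if np.any(layer.values <= 0):
        raise ContractError("linear-scale values must be positive")
    return OmicsLayer(
        layer.datatype,
        layer.analyte_ids,
        layer.sample_ids,
        np.log2(layer.values),
        "log",
        lod_flags=layer.lod_flags,
    )


def detect_pca_outliers(layer: OmicsLayer, n_sd: float = 4.0) -> set[str]:
    """Samples beyond n_sd standard deviations from the mean on PC1 or PC2.

    PCA is taken over samples after centering each analyte; the SD is that of
    all samples' scores on the component.
    """
    if layer.scale != "log":
        raise ContractError("detect_pca_outliers requires a log-scale layer")
    if layer.n_samples < 3:
        raise ContractError("detect_pca_outliers needs at least 3 samples")
    x = layer.values - layer.values.mean(axis=1, keepdims=True)
    # samples x analytes SVD; scores = U * s
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    flagged: set[str] = set()
    for pc in range(min(2, len(s))):
        scores = u[:, pc] * s[pc]
        scores = scores - scores.mean()
        sd = scores.std()
        if sd == 0:
            continue
        for i in np.flatnonzero(np.abs(scores) > n_sd * sd):
            flagged.add(layer.sample_ids[i])
    return flagged


def lod_filter_impute(layer: OmicsLayer) -> tuple[OmicsLayer, PreprocessReport]:
    """Drop analytes with > 50% of samples below the detection limit (strict);
    impute surviving below-LOD metabolite entries to the analyte's minimum
    measured (above-LOD) value; protein values are used as is."""
    if layer.datatype not in TARGETED_DATATYPES:
        raise ContractError("lod_filter_impute applies to protein/metabolite layers")
    if layer.lod_flags is None:
        raise ContractError("lod_filter_impute requires lod_flags")
    frac = layer.lod_flags.mean(axis=1) if layer.n_samples else np.zeros(layer.n_analytes)
    drop = frac > 0.5
    report = PreprocessReport()
    report.add(
        f"lod_filter[{layer.datatype}]",
        removed_analytes=[layer.analyte_ids[i] for i in np.flatnonzero(drop)],
        params={"max_below_lod_fraction": 0.5},
    )
    out = layer.subset_analytes(np.flatnonzero(~drop))
    if layer.datatype == "metabolite":
        values = out.values.copy()
        for a in range(out.n_analytes):
            below = out.lod_flags[a]
            if below.any():
                measured = values[a, ~below]
                values[a, below] = measured.min()
        out = OmicsLayer(
            out.datatype, out.analyte_ids, out.sample_ids, values, out.scale, out.lod_flags
        )
    return out, report


def batch_adjust(
    layer: OmicsLayer, sheet: SampleSheet, preserve: list[str] | None = None
) -> OmicsLayer:
    """Empirical-Bayes location-scale batch adjustment on the log scale.

    Per analyte, values are regressed on batch indicators plus the preserve
    covariates; per-batch location and scale estimates are shrunk toward their
    across-analyte means (parametric priors), the batch component is removed,
    and covariate-explained variation is restored. With a single batch the
    layer is returned unchanged.
    """
    if layer.scale != "log":
        raise ContractError("batch_adjust requires a log-scale layer")
    preserve = list(preserve or [])
    meta = sheet.frame.loc[layer.sample_ids]
    batches = meta["batch"].astype(str).to_numpy()
    levels, batch_idx = np.unique(batches, return_inverse=True)
    counts = np.bincount(batch_idx)
    singles = [levels[b] for b in range(len(levels)) if counts[b] < 2]
    if singles:
        raise ContractError(f"singleton batch(es): {singles}")
    if len(levels) == 1:
        return layer.copy()

    n = layer.n_samples
    n_batch = len(levels)
    # design: batch one-hot (cell-means coding) + preserve covariates
    design_cols = [np.eye(n_batch)[batch_idx]]
    for cov in preserve:
        col = meta[cov]
        if col.dtype.kind in "biufc":
            c = col.to_numpy(dtype=float)
            design_cols.append((c - c.mean())[:, None])
        else:
            vals, inv = np.unique(col.astype(str).to_numpy(), return_inverse=True)
            onehot = np.eye(len(vals))[inv][:, 1:]  # drop reference level
            design_cols.append(onehot)
    X = np.hstack(design_cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ContractError("collinear batch/covariate design")

    Y = layer.values  # analytes x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, analytes)
    grand = (counts / n) @ beta[:n_batch]  # weighted grand mean per analyte
    resid = Y.T - X @ beta  # samples x analytes
    pooled_var = (resid**2).sum(axis=0) / (n - X.shape[1])
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))

    # standardize: remove grand mean and covariate part, rescale by pooled SD
    cov_part = (X[:, n_batch:] @ beta[n_batch:]) if X.shape[1] > n_batch else 0.0
    Z = (Y.T - grand[None, :] - cov_part) / pooled_sd

    # per-batch location/scale on standardized data, shrunk toward
    # across-analyte moments (parametric empirical Bayes)
    adjusted = np.empty_like(Z)
    for b in range(n_batch):
        rows = batch_idx == b
        gamma_hat = Z[rows].mean(axis=0)
        delta_hat = Z[rows].var(axis=0, ddof=1)
        # priors
        gbar, t2 = gamma_hat.mean(), gamma_hat.var()
        dmean, dvar = delta_hat.mean(), delta_hat.var()
        # inverse-gamma prior moments
        if dvar > 0:
            lam = (dmean**2 + 2 * dvar) / dvar
            theta = (dmean**3 + dmean * dvar) / dvar
        else:
            lam, theta = 2.0, dmean
        nb = rows.sum()
        if t2 > 0:
            gamma_star = (nb * t2 * gamma_hat + delta_hat * gbar) / (nb * t2 + delta_hat)
        else:
            gamma_star = np.full_like(gamma_hat, gbar)
        ssq = ((Z[rows] - gamma_star) ** 2).sum(axis=0)
        delta_star = (theta + 0.5 * ssq) / (nb / 2 + lam - 1)
        delta_star = np.maximum(delta_star, 1e-12)
        adjusted[rows] = (Z[rows] - gamma_star) / np.sqrt(delta_star)

    out = adjusted * pooled_sd + grand[None, :] + cov_part
    return OmicsLayer(
        layer.datatype, layer.analyte_ids, layer.sample_ids, out.T, "log",
        lod_flags=None if layer.lod_flags is None else layer.lod_flags.copy(),
    )


def top_variance_filter(layer: OmicsLayer, quantile: float = 0.25) -> OmicsLayer:
    """Retain the ceil(quantile * A) analytes with the largest sample variance;
    ties broken by analyte-ID lexicographic order."""
    if layer.scale != "log":
        raise ContractError("top_variance_filter requires a log-scale layer")
    if not (0.0 < quantile <= 1.0):
        raise ContractError("quantile must lie in (0, 1]")
    n_keep = int(np.ceil(quantile * layer.n_analytes))
    variances = layer.values.var(axis=1, ddof=1) if layer.n_samples > 1 else np.zeros(
        layer.n_analytes
    )
    order = sorted(range(layer.n_analytes), key=lambda i: (-variances[i], layer.analyte_ids[i]))
    keep = sorted(order[:n_keep])  # preserve original analyte order
    return layer.subset_analytes(keep)


def preprocess_layer(
    layer: OmicsLayer,
    sheet: SampleSheet,
    *,
    exclusion_list=(),
    preserve: list[str] | None = None,
    pca_outlier_sd: float = 4.0,
    apply_pca_outliers: bool | None = None,
) -> tuple[OmicsLayer, PreprocessReport, set[str]]:
    """Full per-layer chain: count/LOD filters -> transform -> PCA outliers ->
    batch adjustment. Returns (layer, report, outlier sample IDs).

    PCA outlier removal applies to the rna and protein layers by default (it
    can be forced on/off per layer); outliers are *reported*, and the caller
    removes them from all layers entering fusion so the sample set stays
    common.
    """
    report = PreprocessReport()
    if layer.datatype in COUNT_DATATYPES:
        layer, rep = filter_low_expression(layer, exclusion_list)
        report.steps += rep.steps
        layer = normalize_transform(layer)
    else:
        layer, rep = lod_filter_impute(layer)
        report.steps += rep.steps
        if layer.scale == "linear":
            layer = log_transform(layer)
    if apply_pca_outliers is None:
        apply_pca_outliers = layer.datatype in ("rna", "protein")
    outliers: set[str] = set()
    if apply_pca_outliers and layer.n_samples >= 3:
        outliers = detect_pca_outliers(layer, pca_outlier_sd)
        if outliers:
            keep = [s for s in layer.sample_ids if s not in outliers]
            layer = layer.subset_samples(keep)
        report.add(
            f"pca_outliers[{layer.datatype}]",
            removed_samples=sorted(outliers),
            params={"n_sd": pca_outlier_sd},
        )
    if sheet.frame.loc[layer.sample_ids, "batch"].nunique() > 1:
        layer = batch_adjust(layer, sheet, preserve)
        report.add(f"batch_adjust[{layer.datatype}]", params={"preserve": list(preserve or [])})
    return layer, report, outliers


def preprocess_bundle(
    layers: dict[str, OmicsLayer],
    sheet: SampleSheet,
    *,
    exclusion_list=(),
    preserve: list[str] | None = None,
    variance_quantile: float = 0.25,
    pca_outlier_sd: float = 4.0,
) -> tuple[dict[str, OmicsLayer], PreprocessReport]:
    """Preprocess every layer, drop outlier samples from all fusion inputs,
    restrict to the common (complete-case) sample set, and apply the
    top-variance filter. Output layers share an identical sample ordering."""
    report = PreprocessReport()
    processed: dict[str, OmicsLayer] = {}
    all_outliers: set[str] = set()
    for dt, layer in layers.items():
        out, rep, outliers = preprocess_layer(
            layer,
            sheet,
            exclusion_list=exclusion_list,
            preserve=preserve,
            pca_outlier_sd=pca_outlier_sd,
        )
        processed[dt] = out
        report.steps += rep.steps
        all_outliers |= outliers
    common = [
        s
        for s in sheet.sample_ids
        if s not in all_outliers and all(s in set(l.sample_ids) for l in processed.values())
    ]
    if not common:
        raise ContractError("no samples survive across all layers")
    final = {}
    for dt, layer in processed.items():
        layer = layer.subset_samples(common)
        final[dt] = top_variance_filter(layer, variance_quantile)
    report.add(
        "common_samples",
        removed_samples=sorted(set(sheet.sample_ids) - set(common)),
        params={"variance_quantile": variance_quantile},
    )
    return final, report


__all__ = [
    "PreprocessReport",
    "filter_low_expression",
    "normalize_transform",
    "log_transform",
    "detect_pca_outliers",
    "lod_filter_impute",
    "batch_adjust",
    "top_variance_filter",
    "preprocess_layer",
    "preprocess_bundle",
]
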