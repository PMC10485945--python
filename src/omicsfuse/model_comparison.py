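"""BIC comparison of categorical labelings as predictors of binary
histopathology outcomes.

Three logistic models compete per outcome: the 4-level fused-network cluster
labeling, the 6-level clinical disease grouping, and a merged 4-level disease
grouping (the two control groups pooled; FGR+HDP pooled with severe PE) that
equalizes the level count. Because each model is a saturated categorical
logistic regression, its maximum likelihood has a closed form — the fitted
probability per level is the level's observed positive fraction — which
sidesteps the separation pathologies iterative solvers hit when a level is
all-positive or all-negative. BIC = p ln(n) - 2 lnL with p = number of
levels; lower is better; a difference below 2 is weak evidence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClusterAssignment, ContractError, SampleSheet

MERGE_MAP = {
    "control": "control_any",
    "control_PT": "control_any",
    "severe_PE": "PE_spectrum",
    "FGR_HDP": "PE_spectrum",
    "FGR": "FGR",
    "sPTD": "sPTD",
    # idempotence: merged levels map to themselves
    "control_any": "control_any",
    "PE_spectrum": "PE_spectrum",
}

EVIDENCE_CUTOFFS = ((2.0, "weak"), (6.0, "positive"))  # above 6: strong


def merge_disease_groups(labels) -> np.ndarray:
    """Merge the 6-level disease grouping to 4 levels: both controls pooled,
    FGR+HDP pooled with severe PE; FGR and sPTD unchanged."""
    labels = np.asarray(labels, dtype=object)
    unknown = sorted({l for l in labels if l not in MERGE_MAP})
    if unknown:
        raise ContractError(f"unknown disease level(s): {unknown}")
    return np.array([MERGE_MAP[l] for l in labels], dtype=object)


def fit_logistic_categorical(outcome, predictor) -> tuple[float, int]:
    """Closed-form MLE of a saturated categorical logistic model.

    Returns (log_likelihood, p) with p = number of predictor levels. The
    fitted probability within each level is the observed positive fraction,
    with the 0*ln(0) = 0 convention for perfectly separated levels.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size == 0 or not np.all(np.isin(y, (0.0, 1.0))):
        raise ContractError("outcome must be a nonempty binary vector")
    g = np.asarray(predictor, dtype=object)
    if g.shape != y.shape:
        raise ContractError("outcome and predictor must align")
    levels, idx = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ContractError("need >= 2 predictor levels")
    lnl = 0.0
    for l in range(len(levels)):
        mask = idx == l
        n_l = int(mask.sum())
        y_l = float(y[mask].sum())
        p_hat = y_l / n_l
        if 0.0 < p_hat < 1.0:
            lnl += y_l * np.log(p_hat) + (n_l - y_l) * np.log(1.0 - p_hat)
        # p_hat in {0,1}: perfect fit, contributes 0 (0*ln 0 convention)
    return float(lnl), len(levels)


def bic_score(log_likelihood: float, p: int, n: int) -> float:
    """p ln(n) - 2 lnL; lower is better."""
    if n < 1 or p < 1:
        raise ContractError("need n >= 1 and p >= 1")
    return float(p * np.log(n) - 2.0 * log_likelihood)


@dataclass
class BICRecord:
    outcome: str
    model: str  # clusters_4 | disease_6 | disease_merged_4
    n: int
    p: int
    log_likelihood: float
    bic: float


@dataclass
class EvidenceTable:
    records: list[BICRecord]
    summary: pd.DataFrame  # per outcome: best model, delta_bic, grade

    def to_csv(self, path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "records": [r.__dict__ for r in self.records],
            "summary": self.summary.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def delta_bic_chart_data(self) -> pd.DataFrame:
        """Bar-chart-ready |delta BIC| between best and runner-up per outcome."""
        return self.summary[["outcome", "best_model", "delta_bic", "grade"]].copy()


def _grade(delta: float) -> str:
    for cutoff, name in EVIDENCE_CUTOFFS:
        if delta < cutoff:
            return name
    return "strong"


def compare_models(
    sheet: SampleSheet, clusters: ClusterAssignment, outcomes: list[str] | None = None
) -> EvidenceTable:
    """Fit the three competing labelings per outcome on the identical sample
    set (cluster, disease and outcome all observed) and grade the evidence."""
    outcomes = list(outcomes or sheet.outcome_columns)
    cluster_series = clusters.to_series()
    records: list[BICRecord] = []
    summary_rows = []
    for outcome in outcomes:
        df = sheet.frame[[outcome, "disease_group"]].copy()
        df = df.join(cluster_series, how="inner")
        df = df.dropna()
        y = df[outcome].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            warnings.warn(f"outcome {outcome!r} has a single class; skipped")
            continue
        n = len(df)
        predictors = {
            "clusters_4": df["cluster"].astype(str).to_numpy(dtype=object),
            "disease_6": df["disease_group"].to_numpy(dtype=object),
            "disease_merged_4": merge_disease_groups(df["disease_group"].to_numpy(dtype=object)),
        }
        bics = {}
        for model, g in predictors.items():
            lnl, p = fit_logistic_categorical(y, g)
            b = bic_score(lnl, p, n)
            bics[model] = b
            records.append(BICRecord(outcome, model, n, p, lnl, b))
        ranked = sorted(bics.items(), key=lambda kv: kv[1])
        delta = ranked[1][1] - ranked[0][1]
        summary_rows.append(
            {
                "outcome": outcome,
                "best_model": ranked[0][0],
                "delta_bic": float(delta),
                "grade": _grade(delta),
            }
        )
    return EvidenceTable(records=records, summary=pd.DataFrame(summary_rows))


__all__ = [
    "MERGE_MAP",
    "merge_disease_groups",
    "fit_logistic_categorical",
    "bic_score",
    "BICRecord",
    "EvidenceTable",
    "compare_models",
]
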