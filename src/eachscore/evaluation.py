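"""Discrimination and classification metrics for risk scores, plus the
Revised Cardiac Risk Index comparator.

AUC is the Mann-Whitney probability that a random case outscores a random
control (ties count one half); its 95% CI comes from a stratified
percentile bootstrap — at sub-percent prevalence, resampling cases and
controls separately keeps every replicate two-class.  Operating thresholds
default to the Youden rule (maximize sensitivity + specificity - 1), with
score >= threshold classified positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .synthetic_cohort import SchemaError

__all__ = [
    "EvalReport",
    "RcriInput",
    "roc_auc",
    "classification_metrics",
    "select_threshold",
    "rcri_score",
    "evaluate_scores",
]


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise SchemaError("both outcome classes must be present")


def roc_auc(scores, labels, n_boot: int = 1000, seed: int = 0, ci_level: float = 0.95):
    """Point AUC plus a stratified percentile-bootstrap CI.

    Returns (auc, (lo, hi)).  B resamples draw cases and controls
    separately with replacement, so the case count is fixed in every
    replicate — necessary when cases are rare.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_class(labels)
    auc = float(roc_auc_score(labels, scores))

    rng = np.random.default_rng(seed)
    case_scores = scores[labels == 1]
    ctrl_scores = scores[labels == 0]
    n1, n0 = len(case_scores), len(ctrl_scores)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cs = case_scores[rng.integers(0, n1, n1)]
        co = ctrl_scores[rng.integers(0, n0, n0)]
        boots[b] = roc_auc_score(
            np.concatenate([np.ones(n1, dtype=int), np.zeros(n0, dtype=int)]),
            np.concatenate([cs, co]),
        )
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return auc, (float(lo), float(hi))


def classification_metrics(scores, labels, threshold: float) -> dict:
    """2x2-table metrics at the cut "score >= threshold is positive".

    PPV (NPV) is None — not zero — when no positives (negatives) are
    predicted, since the ratio is undefined there.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_class(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if (tp + fp) > 0 else None,
        "npv": tn / (tn + fn) if (tn + fn) > 0 else None,
    }


def select_threshold(scores, labels, rule: str = "youden") -> float:
    """Operating threshold maximizing Youden's J = sens + spec - 1.

    Candidate cuts are the midpoints between consecutive distinct observed
    scores plus the minimum score (the all-positive cut); ties go to the
    lower threshold.  For perfectly separated classes this returns the
    midpoint of the gap with J = 1.
    """
    if rule != "youden":
        raise ValueError(f"unknown threshold rule {rule!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_class(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    best_t, best_j = None, -np.inf
    for t in candidates:  # ascending: first maximizer = lowest threshold
        m = classification_metrics(scores, labels, t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


@dataclass(frozen=True)
class RcriInput:
    """The six binary components of the Revised Cardiac Risk Index."""

    high_risk_surgery: int
    ischemic_heart_disease: int
    congestive_heart_failure: int
    cerebrovascular_disease: int
    insulin_treatment: int
    creatinine_over_2: int

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")

    @classmethod
    def from_clinical(cls, *, high_risk_surgery=0, ischemic_heart_disease=0,
                      congestive_heart_failure=0, cerebrovascular_disease=0,
                      insulin_treatment=0, creatinine_mg_dl=0.0) -> "RcriInput":
        """Build the indicators from clinical values; the creatinine
        criterion is a level strictly greater than 2 mg/dL."""
        return cls(
            high_risk_surgery=int(bool(high_risk_surgery)),
            ischemic_heart_disease=int(bool(ischemic_heart_disease)),
            congestive_heart_failure=int(bool(congestive_heart_failure)),
            cerebrovascular_disease=int(bool(cerebrovascular_disease)),
            insulin_treatment=int(bool(insulin_treatment)),
            creatinine_over_2=int(creatinine_mg_dl > 2.0),
        )


def rcri_score(record: RcriInput) -> int:
    """Simple count of positive indicators, 0-6."""
    return sum(getattr(record, f) for f in record.__dataclass_fields__)


def evaluate_scores(scores, labels, threshold: float | None = None,
                    n_boot: int = 1000, seed: int = 0) -> EvalReport:
    """Full report: AUC + bootstrap CI and threshold metrics (Youden by
    default, selected on the same data unless a threshold is supplied)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    auc, ci = roc_auc(scores, labels, n_boot=n_boot, seed=seed)
    if threshold is None:
        threshold = select_threshold(scores, labels)
    m = classification_metrics(scores, labels, threshold)
    return EvalReport(
        auc=auc, auc_ci=ci, threshold=float(threshold),
        accuracy=m["accuracy"], sensitivity=m["sensitivity"], specificity=m["specificity"],
        ppv=m["ppv"], npv=m["npv"],
        n_cases=int(np.sum(labels == 1)), n_controls=int(np.sum(labels == 0)),
    )
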