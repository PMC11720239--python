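"""Evaluation metrics and the cohort demographic summary.

Accuracy and AUC score each binary task separately; absolute accuracy
scores the composite outcome (both labels right at once); the phi
coefficient between the two binary outcome labels quantifies how
inter-correlated the two prediction tasks are.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

from .core_io import ClinicalTable, LabelPair


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("length mismatch")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )


def accuracy(cm: ConfusionMatrix) -> float:
    """ACC = (TP + TN) / (TP + FN + FP + TN)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties between classes count 0.5.

    Equals the fraction of (positive, negative) pairs whose scores are
    correctly ordered.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("length mismatch")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def absolute_accuracy(pred: LabelPair, truth: LabelPair) -> float:
    """Fraction of samples whose BOTH predicted outcome labels are correct.

    Bounded above by the smaller of the two per-task accuracies.
    """
    if len(pred) != len(truth):
        raise ValueError("length mismatch between predicted and true label pairs")
    if len(pred) == 0:
        raise ValueError("empty label pairs")
    both = (pred.survival_label == truth.survival_label) & (
        pred.vital_label == truth.vital_label
    )
    return float(both.mean())


def label_correlation(labels: LabelPair) -> float:
    """Pearson correlation between the two binary label vectors.

    For two binaries this is the phi coefficient of their 2x2 contingency
    table; a value near 1 means the two prognostic tasks are strongly
    inter-correlated.
    """
    a = labels.survival_label.astype(float)
    b = labels.vital_label.astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("label correlation undefined for a constant label vector")
    return float(np.corrcoef(a, b)[0, 1])


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (table formatting convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def demographic_summary(c: ClinicalTable) -> dict:
    """Cohort characteristics table: counts, percentages and count ratios.

    For every categorical clinical variable present, reports the category
    frequency and percentage of the cohort (2 decimals, half-up); also the
    male:female and dead:alive count ratios (2 decimals) when available.
    """
    n = c.n_samples
    categorical = [
        col
        for col in ("gender", "race", "inss_stage", "mycn_status", "risk_group", "vital_status")
        if col in c.df.columns
    ]
    variables: dict[str, list[dict]] = {}
    for col in categorical:
        vals = c.df[col].astype(str).str.strip()
        counts = vals.value_counts()
        variables[col] = [
            {"category": cat, "count": int(cnt), "percentage": _round2(100.0 * cnt / n)}
            for cat, cnt in counts.items()
        ]
    ratios: dict[str, float] = {}
    if "gender" in c.df.columns:
        g = c.df["gender"].astype(str).str.strip().str.lower()
        males, females = int((g == "male").sum()), int((g == "female").sum())
        if females > 0:
            ratios["male_female"] = _round2(males / females)
    v = c.df["vital_status"].astype(str).str.strip().str.lower()
    dead, alive = int((v == "dead").sum()), int((v == "alive").sum())
    if alive > 0:
        ratios["dead_alive"] = _round2(dead / alive)
    summary: dict = {"n": n, "variables": variables, "ratios": ratios}
    age = np.asarray(c.df["age_days"], dtype=float) / 365.25
    surv = np.asarray(c.df["survival_years"], dtype=float)
    if np.isfinite(age).any():
        summary["age_years_mean"] = _round2(float(np.nanmean(age)))
    if np.isfinite(surv).any():
        summary["survival_years_mean"] = _round2(float(np.nanmean(surv)))
        summary["survival_years_median"] = _round2(float(np.nanmedian(surv)))
    return summary
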