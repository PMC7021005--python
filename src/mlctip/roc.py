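"""ROC analysis of QA detectability.

The question: does the gamma pass rate separate deliveries compared against
the clinical beam model (negatives, "should pass") from deliveries compared
against perturbed models (positives, "should fail")?  Low pass rates flag a
failure, so the decision rule is ``pass_rate <= threshold``; sweeping the
threshold over all observed pass rates traces the ROC curve, and the
trapezoidal area under it (tie-aware, equal to the Mann-Whitney concordance
probability) summarizes detectability: 0.5 is chance, 1.0 perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mlc import BeamModelParams

__all__ = ["QAComparisonRecord", "ROCCurve", "label_records", "roc_curve", "auc_from_scores"]


@dataclass
class QAComparisonRecord:
    plan_id: str
    candidate_model_id: str
    offset_mm: float
    width_mm: float
    criteria: str
    pass_rate: float
    replicate_seed: int
    label: int | None = None  # 0 = negative (clinical model), 1 = positive (perturbed)


@dataclass
class ROCCurve:
    """Threshold sweep over the QA statistic with trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def label_records(
    records: list[QAComparisonRecord], clinical: BeamModelParams
) -> list[QAComparisonRecord]:
    """Label records: exact (offset, width) match with the clinical model -> negative."""
    for rec in records:
        is_clinical = (
            rec.offset_mm == clinical.leaf_tip_offset_mm
            and rec.width_mm == clinical.leaf_tip_width_mm
        )
        rec.label = 0 if is_clinical else 1
    if not any(r.label == 0 for r in records):
        raise ValueError("no negative (clinical-model) records present")
    return records


def roc_curve(scores, labels=None) -> ROCCurve:
    """ROC for the rule "flag positive when score <= threshold".

    Accepts labeled :class:`QAComparisonRecord` objects or parallel
    ``scores`` / ``labels`` arrays.  Thresholds sweep the distinct observed
    scores (tied scores grouped), the curve is anchored at (0, 0) and (1, 1),
    and the AUC is the trapezoidal area.
    """
    if labels is None:
        records = list(scores)
        if any(r.label is None for r in records):
            raise ValueError("records must be labeled first")
        s = np.array([r.pass_rate for r in records], dtype=float)
        y = np.array([r.label for r in records], dtype=int)
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve needs at least one positive and one negative")

    thresholds = np.unique(s)
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        flagged = s <= t
        tpr.append(float((flagged & (y == 1)).sum()) / n_pos)
        fpr.append(float((flagged & (y == 0)).sum()) / n_neg)
    tpr_a = np.array(tpr)
    fpr_a = np.array(fpr)
    # the final threshold flags everything, so the sweep ends at (1, 1)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return ROCCurve(thresholds, tpr_a, fpr_a, auc)


def auc_from_scores(pos_scores, neg_scores) -> float:
    """AUC of "positives score lower" from two score samples."""
    s = np.concatenate([np.asarray(pos_scores, float), np.asarray(neg_scores, float)])
    y = np.concatenate([np.ones(len(pos_scores), int), np.zeros(len(neg_scores), int)])
    return roc_curve(s, y).auc
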