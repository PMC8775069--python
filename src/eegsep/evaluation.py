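"""Subject-wise leave-one-out cross-validation and patient-based metrics.

Epoch-level probabilities (sigmoid outputs, ES = 1) are aggregated into a
per-subject label by majority vote over thresholded epochs; subjects are then
scored against their true class.  The metric suite treats **PNES as the
positive class**: TP counts PNES subjects classified correctly and TN counts
ES subjects classified correctly, while the epoch-level sigmoid encodes
ES = 1.  Both conventions are deliberate and tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .synthetic import ES, PNES

POSITIVE_CLASS = PNES


@dataclass(frozen=True)
class ConfusionMatrix:
    """Subject-level 2x2 counts with PNES as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Patient-based classification metrics, as proportions in [0, 1]
    (kappa in [-1, 1]).  ``undefined`` lists metrics whose denominator was
    zero and were reported as 0."""

    accuracy: float
    precision: float
    recall: float
    f_measure: float
    cohens_kappa: float
    auc: Optional[float] = None
    undefined: Tuple[str, ...] = ()

    def as_dict(self, percent: bool = False) -> Dict[str, float]:
        scale = 100.0 if percent else 1.0
        out = {
            "accuracy": self.accuracy * scale,
            "precision": self.precision * scale,
            "recall": self.recall * scale,
            "f_measure": self.f_measure * scale,
            "cohens_kappa": self.cohens_kappa * scale,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion_from_labels(true_labels: Sequence[str],
                          pred_labels: Sequence[str]) -> ConfusionMatrix:
    """Count subject-level outcomes (PNES positive)."""
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors must have equal length")
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    return ConfusionMatrix(
        tp=int(np.sum((t == PNES) & (p == PNES))),
        tn=int(np.sum((t == ES) & (p == ES))),
        fp=int(np.sum((t == ES) & (p == PNES))),
        fn=int(np.sum((t == PNES) & (p == ES))),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall, F-measure and Cohen's kappa from counts.

    kappa uses the 2x2 closed form
    ``2*(TP*TN - FN*FP) / ((TP+FP)*(FP+TN) + (TP+FN)*(FN+TN))``.
    Zero denominators yield 0 with the metric name recorded in
    ``undefined`` (and a warning).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    undefined: List[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    accuracy = (tp + tn) / cm.total
    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f_measure = safe(2 * precision * recall, precision + recall, "f_measure")
    kappa = safe(2.0 * (tp * tn - fn * fp),
                 (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn),
                 "cohens_kappa")
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f_measure=f_measure, cohens_kappa=kappa,
                         undefined=tuple(undefined))


def loocv_folds(subject_ids: Sequence[str], class_labels: Sequence[str]
                ) -> List[Tuple[List[str], str]]:
    """One fold per subject: (training subject ids, held-out subject id).

    The cohort itself must contain both classes.  A training fold can still
    end up single-class when a class has only one subject (e.g. a 2-subject
    cohort); that degenerate case is rejected downstream when the estimator
    is fitted, so that fold *generation* stays a pure partition.
    """
    if len(subject_ids) != len(class_labels):
        raise ValueError("subject_ids and class_labels must align")
    if len(subject_ids) < 2:
        raise ValueError("need at least 2 subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject ids must be unique")
    if len(set(class_labels)) < 2:
        raise ValueError("cohort contains a single class")
    ids = list(subject_ids)
    return [([s for s in ids if s != test_id], test_id) for test_id in ids]


def subject_label(epoch_probabilities: np.ndarray) -> Tuple[str, float]:
    """Majority vote over thresholded epoch probabilities.

    Epochs with probability > 0.5 vote ES, otherwise PNES.  The subject is
    assigned the class holding more than half of the votes; an exact 50/50
    tie is broken by the mean probability against 0.5.  Returns the label
    and the fraction of epochs voting for it.
    """
    p = np.asarray(epoch_probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("epoch probability vector is empty")
    es_frac = float(np.mean(p > 0.5))
    if es_frac > 0.5:
        return ES, es_frac
    if es_frac < 0.5:
        return PNES, 1.0 - es_frac
    label = ES if float(np.mean(p)) > 0.5 else PNES
    return label, 0.5


def roc_auc(subject_scores: Sequence[float], true_labels: Sequence[str]
            ) -> float:
    """Area under the subject-level ROC (scores oriented toward ES)."""
    labels = np.asarray(true_labels)
    y = (labels == ES).astype(int)
    if len(set(y)) < 2:
        raise ValueError("roc_auc requires both classes")
    return float(roc_auc_score(y, np.asarray(subject_scores, dtype=float)))


@dataclass
class LOOCVResult:
    """Per-subject table plus the aggregate confusion matrix and metrics."""

    per_subject: pd.DataFrame  # subject_id, true, predicted, mean_prob, fraction
    confusion: ConfusionMatrix
    metrics: MetricsReport


def run_loocv(
    subject_ids: Sequence[str],
    class_labels: Sequence[str],
    epoch_inputs: Dict[str, np.ndarray],
    estimator_factory: Callable[[], object],
    progress: Optional[Callable[[str], None]] = None,
) -> LOOCVResult:
    """Run subject-wise LOOCV with an estimator exposing
    ``fit(X, y)`` / ``predict_proba_epochs(X)``.

    ``epoch_inputs`` maps subject id to that subject's per-epoch input array
    (first axis = epochs).  Per-epoch labels are 1 for ES and 0 for PNES.
    The subject-level score fed to the ROC is the mean epoch probability.
    """
    labels = dict(zip(subject_ids, class_labels))
    folds = loocv_folds(subject_ids, class_labels)
    rows = []
    for train_ids, test_id in folds:
        if progress is not None:
            progress(test_id)
        X = np.concatenate([epoch_inputs[s] for s in train_ids], axis=0)
        y = np.concatenate([
            np.full(len(epoch_inputs[s]), 1.0 if labels[s] == ES else 0.0)
            for s in train_ids
        ])
        est = estimator_factory()
        est.fit(X, y)
        probs = est.predict_proba_epochs(epoch_inputs[test_id])
        pred, frac = subject_label(probs)
        rows.append({
            "subject_id": test_id,
            "true": labels[test_id],
            "predicted": pred,
            "mean_prob": float(np.mean(probs)),
            "fraction": frac,
        })
    per_subject = pd.DataFrame(rows)
    cm = confusion_from_labels(per_subject["true"], per_subject["predicted"])
    metrics = compute_metrics(cm)
    try:
        auc = roc_auc(per_subject["mean_prob"], per_subject["true"])
        metrics = MetricsReport(**{**metrics.__dict__, "auc": auc})
    except ValueError:
        pass
    return LOOCVResult(per_subject=per_subject, confusion=cm, metrics=metrics)
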