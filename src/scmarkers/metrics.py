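"""Multiclass performance reporting.

Metrics follow the classical one-vs-rest decomposition of a confusion
matrix: for each class, TP/FP/FN/TN are counted treating that class as
positive, giving

    accuracy  = (TP + TN) / (TP + TN + FP + FN)   (multiclass: trace / total)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Macro averages are unweighted class means (insensitive to class imbalance);
micro averages are also emitted for transparency.  One-vs-rest ROC AUC is
computed from the rank statistic (Mann-Whitney U with midranks for ties),
which equals trapezoidal integration of the ROC curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "roc_curve_points",
    "evaluate_predictions",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = true class, columns = predicted class."""

    classes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=object)
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValidationError("confusion counts must be square over the class list")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def to_csv(self, path) -> None:
        self.to_df().to_csv(path, index_label="true\\pred")


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count (true, predicted) label pairs over an ordered class list."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred differ in length")
    if classes is None:
        classes = np.array(sorted(set(y_true) | set(y_pred)), dtype=object)
    else:
        classes = np.asarray(classes, dtype=object)
    lookup = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValidationError(f"labels not in class list: {sorted(map(str, unknown))}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[lookup[t], lookup[p]] += 1
    return ConfusionMatrix(classes, counts)


@dataclass
class EvaluationReport:
    """Scalar metrics plus per-class breakdown and the confusion matrix."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict
    confusion: ConfusionMatrix
    precision_micro: float | None = None
    recall_micro: float | None = None
    f1_micro: float | None = None
    auc_macro: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "precision_micro": self.precision_micro,
            "recall_micro": self.recall_micro,
            "f1_micro": self.f1_micro,
            "auc_macro": self.auc_macro,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": {
                "classes": [str(c) for c in self.confusion.classes],
                "counts": self.confusion.counts.tolist(),
            },
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _safe_div(num: float, den: float, what: str, cls) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls!r} (zero denominator); using 0")
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> EvaluationReport:
    """Accuracy and per-class / macro / micro precision, recall and F1.

    Per class, TP is the diagonal entry, FP the rest of its column, FN the
    rest of its row, TN everything else.  Zero denominators yield 0 with a
    warning.  AUC fields are left unset (they need probabilities).
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    per_class = {}
    precisions, recalls, f1s = [], [], []
    for i, cls in enumerate(cm.classes):
        p = _safe_div(tp[i], tp[i] + fp[i], "precision", cls)
        r = _safe_div(tp[i], tp[i] + fn[i], "recall", cls)
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        per_class[cls] = {"precision": p, "recall": r, "f1": f1}
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    micro_p = float(tp.sum() / (tp.sum() + fp.sum()))  # = accuracy for single-label
    micro_r = float(tp.sum() / (tp.sum() + fn.sum()))
    micro_f1 = 0.0 if micro_p + micro_r == 0 else 2 * micro_p * micro_r / (micro_p + micro_r)
    return EvaluationReport(
        accuracy=float(tp.sum() / total),
        precision_macro=float(np.mean(precisions)),
        recall_macro=float(np.mean(recalls)),
        f1_macro=float(np.mean(f1s)),
        per_class=per_class,
        confusion=cm,
        precision_micro=micro_p,
        recall_micro=micro_r,
        f1_micro=micro_f1,
    )


def roc_auc(y_true, scores, classes) -> tuple[dict, float]:
    """One-vs-rest AUC per class via the rank statistic, plus the macro mean.

    ``scores`` holds one probability row per cell, columns aligned with
    ``classes``.  The AUC for a class is the Mann-Whitney U statistic of its
    probability column, with midranks for ties — identical to trapezoidal
    integration of the ROC curve.  Classes absent from ``y_true`` get NaN and
    are excluded from the macro average with a warning.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes, dtype=object)
    if scores.shape != (y_true.size, classes.size):
        raise ValidationError("scores must be (n_cells, n_classes)")
    per_class: dict = {}
    aucs = []
    for j, cls in enumerate(classes):
        pos = y_true == cls
        n_pos = int(pos.sum())
        n_neg = y_true.size - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {cls!r} absent from one side; AUC undefined")
            per_class[cls] = float("nan")
            continue
        ranks = rankdata(scores[:, j])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class[cls] = float(auc)
        aucs.append(auc)
    macro = float(np.mean(aucs)) if aucs else float("nan")
    return per_class, macro


def roc_curve_points(y_true, scores, classes) -> pd.DataFrame:
    """ROC curve coordinates per class: columns class, fpr, tpr, threshold."""
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    frames = []
    for j, cls in enumerate(np.asarray(classes, dtype=object)):
        pos = (y_true == cls).astype(int)
        if pos.sum() in (0, pos.size):
            continue
        fpr, tpr, thr = roc_curve(pos, scores[:, j])
        frames.append(
            pd.DataFrame({"class": str(cls), "fpr": fpr, "tpr": tpr, "threshold": thr})
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["class", "fpr", "tpr", "threshold"]
    )


def evaluate_predictions(
    y_true, y_pred, classes, proba=None, metadata: dict | None = None
) -> EvaluationReport:
    """Full report: confusion-derived metrics plus (optionally) one-vs-rest AUC."""
    cm = confusion(y_true, y_pred, classes)
    report = metrics_from_confusion(cm)
    if proba is not None:
        per_class_auc, macro = roc_auc(y_true, proba, classes)
        for cls, auc in per_class_auc.items():
            report.per_class[cls]["auc"] = auc
        report.auc_macro = macro
    report.metadata = dict(metadata or {})
    report.metadata.setdefault("averaging", "macro (unweighted class mean); micro emitted alongside")
    report.metadata.setdefault("auc_definition", "one-vs-rest, macro average across classes")
    return report
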