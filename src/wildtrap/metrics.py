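"""Evaluation statistics for multiclass species classification.

Top-1 accuracy, per-class precision / recall / F1, macro F1 and the
confusion matrix, with the conventions used throughout the pipeline:

* precision = TP / (TP + FP), recall = TP / (TP + FN),
  F1 = 2·precision·recall / (precision + recall);
* any 0/0 denominator yields 0 — a class that is present in the test
  set but never predicted scores 0, which deliberately penalizes models
  that ignore rare classes;
* the single reported F1 per model is the **macro** (unweighted) mean
  of per-class F1 over classes with nonzero test support.  Macro
  averaging is what lets a model show high accuracy alongside a much
  lower F1 on a long-tailed test set (micro-averaged F1 is identical to
  accuracy in single-label multiclass classification).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .catalog import ClassRecallRow

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "class_prf",
    "report",
    "micro_f1",
    "per_class_recall_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows index the true class, columns the
    predicted class, both in ``labels`` order."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in confusion matrix") from None


@dataclass(frozen=True)
class MetricsReport:
    top1_accuracy: float
    per_class: Mapping[str, Mapping[str, float]]  # label -> precision/recall/f1/support
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "top1_accuracy": self.top1_accuracy,
            "macro_f1": self.macro_f1,
            "per_class": {c: dict(v) for c, v in self.per_class.items()},
        }


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              label_order: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix; any label outside ``label_order`` is an
    error."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    idx = {c: i for i, c in enumerate(label_order)}
    k = len(idx)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in idx:
            raise ValueError(f"true label {t!r} outside label order")
        if p not in idx:
            raise ValueError(f"predicted label {p!r} outside label order")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(tuple(label_order), counts)


def _prf_from_counts(tp: int, fp: int, fn: int) -> dict[str, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


def class_prf(cm: ConfusionMatrix, label: str) -> dict[str, float]:
    """Precision, recall and F1 for one class (0/0 convention → 0)."""
    i = cm.index(label)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum()) - tp
    fn = int(cm.counts[i, :].sum()) - tp
    return _prf_from_counts(tp, fp, fn)


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Full metrics report: top-1 accuracy = trace/total; macro F1 over
    classes with nonzero test support."""
    if cm.total == 0:
        raise ValueError("cannot report metrics on an empty confusion matrix")
    per_class = {}
    f1s = []
    for i, label in enumerate(cm.labels):
        support = int(cm.counts[i, :].sum())
        vals = class_prf(cm, label)
        vals["support"] = support
        per_class[label] = vals
        if support > 0:
            f1s.append(vals["f1"])
    return MetricsReport(
        top1_accuracy=float(np.trace(cm.counts)) / cm.total,
        per_class=per_class,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
    )


def micro_f1(cm: ConfusionMatrix) -> float:
    """Micro-averaged F1 (pooled TP/FP/FN).  In single-label multiclass
    classification this equals top-1 accuracy — a useful sanity
    identity."""
    tp = int(np.trace(cm.counts))
    fp = cm.total - tp  # every off-diagonal entry is one FP and one FN
    return _prf_from_counts(tp, fp, fp)["f1"]


def per_class_recall_table(cm: ConfusionMatrix, train_counts: Mapping[str, int],
                           model_name: str = "model") -> list[ClassRecallRow]:
    """Per-class recall report in the printed-table dialect: one row per
    class with its training count, test support and recall.  Classes
    with zero test support are reported with recall 0."""
    missing = [c for c in cm.labels if c not in train_counts]
    if missing:
        raise ValueError(f"train_counts missing classes: {missing}")
    rows = []
    for i, label in enumerate(cm.labels):
        support = int(cm.counts[i, :].sum())
        rows.append(ClassRecallRow(
            class_label=label,
            n_train=int(train_counts[label]),
            n_test=support,
            recall_by_model={model_name: class_prf(cm, label)["recall"]},
        ))
    return rows
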