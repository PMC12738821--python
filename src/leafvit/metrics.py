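"""Confusion-matrix based evaluation: per-class one-vs-rest precision,
specificity, F1, recall and accuracy, overall accuracy, and per-class ROC
curves with AUC.

Row convention: confusion rows are the true class, columns the prediction,
so row sums equal per-class test supports. A class absent from the test set
has undefined recall/F1; those entries are reported as ``None`` (missing),
never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc, confusion_matrix as _sk_confusion, roc_curve


@dataclass
class MetricsReport:
    class_names: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float | None]]
    overall_accuracy: float
    roc: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
            "roc": {
                c: {"auc": r["auc"]} for c, r in self.roc.items()
            },
        }

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_markdown(self) -> str:
        cols = ["Precision", "Specificity", "F1-score", "Recall", "Accuracy"]
        keys = ["precision", "specificity", "f1", "recall", "accuracy"]
        lines = ["| Category | " + " | ".join(cols) + " |",
                 "|" + "---|" * (len(cols) + 1)]
        for c in self.class_names:
            vals = []
            for k in keys:
                v = self.per_class[c][k]
                vals.append("—" if v is None else f"{v:.4f}")
            lines.append(f"| {c} | " + " | ".join(vals) + " |")
        lines.append(f"\nOverall accuracy: {self.overall_accuracy:.4f}")
        return "\n".join(lines)

    def confusion_to_csv(self, path: str) -> None:
        header = "," + ",".join(self.class_names)
        rows = [
            f"{c}," + ",".join(str(int(v)) for v in self.confusion[i])
            for i, c in enumerate(self.class_names)
        ]
        with open(path, "w") as fh:
            fh.write(header + "\n" + "\n".join(rows) + "\n")


def binary_counts(confusion: np.ndarray, c: int) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) for class c one-vs-rest."""
    tp = int(confusion[c, c])
    fp = int(confusion[:, c].sum() - tp)
    fn = int(confusion[c, :].sum() - tp)
    tn = int(confusion.sum() - tp - fp - fn)
    return tp, fp, fn, tn


def _safe_div(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probs: np.ndarray | None = None,
    class_names: Sequence[str] | None = None,
) -> MetricsReport:
    """Build the full report from labels, predictions and (optionally) the
    per-class probabilities used for ROC curves (one-vs-rest threshold sweep)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n_classes = probs.shape[1] if probs is not None else int(max(y_true.max(), y_pred.max())) + 1
    if class_names is None:
        class_names = tuple(f"class_{i}" for i in range(n_classes))
    class_names = tuple(class_names)
    labels = np.arange(len(class_names))
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    total = cm.sum()
    per_class: dict[str, dict[str, float | None]] = {}
    for c, name in enumerate(class_names):
        tp, fp, fn, tn = binary_counts(cm, c)
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        specificity = _safe_div(tn, tn + fp)
        if precision is None or recall is None or (precision + recall) == 0:
            f1 = None if (precision is None or recall is None) else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[name] = {
            "precision": precision,
            "specificity": specificity,
            "f1": f1,
            "recall": recall,
            "accuracy": _safe_div(tp + tn, total),
            "support": int(cm[c].sum()),
        }
    report = MetricsReport(
        class_names=class_names,
        confusion=cm,
        per_class=per_class,
        overall_accuracy=float(np.trace(cm) / total) if total else float("nan"),
    )
    if probs is not None:
        for c, name in enumerate(class_names):
            binary = (y_true == c).astype(int)
            if binary.min() == binary.max():
                report.roc[name] = {"fpr": None, "tpr": None, "auc": None}
                continue
            fpr, tpr, thr = roc_curve(binary, probs[:, c])
            report.roc[name] = {
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
                "thresholds": thr.tolist(),
                "auc": float(auc(fpr, tpr)),
            }
    return report
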