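"""Multiclass evaluation: confusion matrix and per-class/macro metrics.

Per class k, one-vs-rest counts (tp, fp, fn, tn) are read off the confusion
matrix and turned into

    accuracy    = (tp + tn) / (tp + fp + fn + tn)
    sensitivity = tp / (tp + fn)          (recall, true positive rate)
    precision   = tp / (tp + fp)          (positive predictive value)
    f1          = 2 * precision * sensitivity / (precision + sensitivity)

Zero-denominator ratios are reported as NaN with a warning, never silently
as zero.  The report carries both the per-class one-vs-rest accuracies and
the overall (micro) accuracy trace/total, plus unweighted macro averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

__all__ = ["ClassMetrics", "MetricsReport", "confusion", "class_metrics", "macro_report"]


def confusion(true_labels, predicted_labels, class_order) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    order = [str(c) for c in class_order]
    t = [str(x) for x in true_labels]
    p = [str(x) for x in predicted_labels]
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    known = set(order)
    for name, vec in (("true", t), ("predicted", p)):
        unknown = [x for x in vec if x not in known]
        if unknown:
            raise ValueError(f"unknown {name} label {unknown[0]!r}")
    return _sk_confusion(t, p, labels=order)


@dataclass(frozen=True)
class ClassMetrics:
    label: str
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    precision: float
    f1: float


def _safe_ratio(num: float, den: float, what: str, label: str) -> float:
    if den == 0:
        warnings.warn(
            f"{what} undefined for class {label!r} (zero denominator); reporting NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("nan")
    return num / den


def class_metrics(conf: np.ndarray, k: int, class_order=None) -> ClassMetrics:
    """One-vs-rest counts and the four ratios for class index ``k``."""
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {conf.shape}")
    n = conf.shape[0]
    if not 0 <= k < n:
        raise IndexError(f"class index {k} out of range for {n} classes")
    label = str(class_order[k]) if class_order is not None else str(k)
    total = int(conf.sum())
    tp = int(conf[k, k])
    fp = int(conf[:, k].sum()) - tp
    fn = int(conf[k, :].sum()) - tp
    tn = total - tp - fp - fn
    accuracy = _safe_ratio(tp + tn, total, "accuracy", label)
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", label)
    precision = _safe_ratio(tp, tp + fp, "precision", label)
    if np.isnan(sensitivity) or np.isnan(precision) or precision + sensitivity == 0:
        if not (np.isnan(sensitivity) or np.isnan(precision)):
            warnings.warn(
                f"f1 undefined for class {label!r} (zero denominator); reporting NaN",
                RuntimeWarning,
                stacklevel=2,
            )
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return ClassMetrics(label, tp, fp, fn, tn, accuracy, sensitivity, precision, f1)


@dataclass(frozen=True)
class MetricsReport:
    """Confusion matrix, per-class records, macro averages, micro accuracy."""

    confusion: np.ndarray
    class_order: tuple[str, ...]
    per_class: tuple[ClassMetrics, ...]
    macro_accuracy: float
    macro_sensitivity: float
    macro_precision: float
    macro_f1: float
    micro_accuracy: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": m.label,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "tn": m.tn,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "precision": m.precision,
                "f1": m.f1,
            }
            for m in self.per_class
        ]
        rows.append(
            {
                "class": "macro",
                "accuracy": self.macro_accuracy,
                "sensitivity": self.macro_sensitivity,
                "precision": self.macro_precision,
                "f1": self.macro_f1,
            }
        )
        rows.append({"class": "micro", "accuracy": self.micro_accuracy})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def confusion_to_csv(self, path) -> None:
        pd.DataFrame(
            self.confusion, index=list(self.class_order), columns=list(self.class_order)
        ).rename_axis("true\\pred").to_csv(path)

    def pretty(self) -> str:
        lines = [self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}")]
        lines.append(f"\nmicro accuracy: {self.micro_accuracy:.4f}")
        return "\n".join(lines)


def macro_report(conf: np.ndarray, class_order=None) -> MetricsReport:
    """Unweighted macro averages of the per-class metrics plus micro accuracy."""
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {conf.shape}")
    n = conf.shape[0]
    if n < 2:
        raise ValueError("macro report needs at least two classes")
    order = tuple(str(c) for c in class_order) if class_order is not None else tuple(
        str(k) for k in range(n)
    )
    per_class = tuple(class_metrics(conf, k, order) for k in range(n))
    total = conf.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return MetricsReport(
        confusion=conf,
        class_order=order,
        per_class=per_class,
        macro_accuracy=float(np.mean([m.accuracy for m in per_class])),
        macro_sensitivity=float(np.mean([m.sensitivity for m in per_class])),
        macro_precision=float(np.mean([m.precision for m in per_class])),
        macro_f1=float(np.mean([m.f1 for m in per_class])),
        micro_accuracy=float(np.trace(conf) / total),
    )
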