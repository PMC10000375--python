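"""Classification metrics and evaluation reports.

Counts follow the usual one-vs-rest convention per class: T1 true
positives, T2 true negatives, F1 false positives, F2 false negatives.
Accuracy is (T1+T2)/total, precision T1/(T1+F1), recall T1/(T1+F2),
F-score the harmonic mean 2PR/(P+R), and the error rate the fraction of
misclassified samples (so accuracy + error rate = 1 on pooled
predictions).  Macro metrics average per-class values, skipping classes
whose denominator is undefined; micro metrics pool the counts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "accuracy",
    "precision",
    "recall",
    "f_score",
    "error_rate",
    "confusion_matrix",
    "evaluate",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    t1: int  # true positives
    t2: int  # true negatives
    f1: int  # false positives
    f2: int  # false negatives

    def __post_init__(self) -> None:
        if min(self.t1, self.t2, self.f1, self.f2) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.t1 + self.t2 + self.f1 + self.f2


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for zero total count")
    return (c.t1 + c.t2) / c.total


def precision(c: ConfusionCounts) -> float | None:
    """T1/(T1+F1); None when undefined (no positive predictions)."""
    denom = c.t1 + c.f1
    return c.t1 / denom if denom else None


def recall(c: ConfusionCounts) -> float | None:
    """T1/(T1+F2); None when undefined (no positive samples)."""
    denom = c.t1 + c.f2
    return c.t1 / denom if denom else None


def f_score(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when p = r = 0."""
    if p == 0 and r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def error_rate(n_errors: int, n_samples: int) -> float:
    if n_samples <= 0:
        raise ValueError(f"n_samples must be > 0, got {n_samples}")
    return n_errors / n_samples


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t), int(p)] += 1
    return cm


@dataclass
class EvalReport:
    """Per-class and aggregate metrics for one evaluation run."""

    class_names: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float | None]]
    macro: dict[str, float]
    micro_accuracy: float
    overall_accuracy: float
    error_rate: float
    n_samples: int
    computation_time_s: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "micro_accuracy": self.micro_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "error_rate": self.error_rate,
            "n_samples": self.n_samples,
            "computation_time_s": self.computation_time_s,
            "extras": self.extras,
        }


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    class_names: list[str],
    started_at: float | None = None,
) -> EvalReport:
    """Build a full report from integer-coded predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = y_true.size
    m = len(class_names)
    cm = confusion_matrix(y_true, y_pred, m)

    per_class: dict[str, dict[str, float | None]] = {}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for k, name in enumerate(class_names):
        t1 = int(cm[k, k])
        f1 = int(cm[:, k].sum() - t1)
        f2 = int(cm[k, :].sum() - t1)
        t2 = int(n - t1 - f1 - f2)
        c = ConfusionCounts(t1, t2, f1, f2)
        p, r = precision(c), recall(c)
        per_class[name] = {
            "accuracy": accuracy(c),
            "precision": p,
            "recall": r,
            "f_score": f_score(p, r) if p is not None and r is not None else None,
        }
        pooled = ConfusionCounts(
            pooled.t1 + t1, pooled.t2 + t2, pooled.f1 + f1, pooled.f2 + f2
        )

    macro = {}
    for key in ("accuracy", "precision", "recall", "f_score"):
        vals = [v[key] for v in per_class.values() if v[key] is not None]
        macro[key] = float(np.mean(vals)) if vals else 0.0

    n_correct = int(np.trace(cm))
    overall = n_correct / n if n else 0.0
    return EvalReport(
        class_names=list(class_names),
        confusion=cm,
        per_class=per_class,
        macro=macro,
        micro_accuracy=accuracy(pooled),
        overall_accuracy=overall,
        error_rate=error_rate(n - n_correct, n),
        n_samples=n,
        computation_time_s=(time.perf_counter() - started_at) if started_at else 0.0,
    )
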