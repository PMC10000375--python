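"""Lesion-count severity grading via conditional-entropy thresholds.

Severity (mild / moderate / severe) is assumed monotone in the number of
lesions.  Two integer cut points (t1 < t2) bin the counts into three
groups; the cut points are fitted by exhaustively minimizing the
conditional entropy of the severity label given the bin,

    H(label | bin) = sum_b p(b) * H(label | b)          (base-2 logs),

over every pair of observed count values.  Ties break toward the smallest
(t1, t2).  Grading convention: count <= t1 -> mild, t1 < count <= t2 ->
moderate, count > t2 -> severe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SEVERITY_CLASSES",
    "SeverityThresholds",
    "fit_thresholds",
    "grade",
    "conditional_entropy",
    "weighted_count",
]

SEVERITY_CLASSES = ("mild", "moderate", "severe")


@dataclass
class SeverityThresholds:
    t1: int
    t2: int
    fitted_entropy: float
    class_names: tuple[str, ...] = SEVERITY_CLASSES

    def __post_init__(self) -> None:
        if not 0 <= self.t1 < self.t2:
            raise ValueError(f"need 0 <= t1 < t2, got t1={self.t1}, t2={self.t2}")


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy (bits) of a label sample; 0*log0 = 0."""
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(counts: np.ndarray, labels: np.ndarray, t1: int, t2: int) -> float:
    """H(label | bin) under the three-bin split at (t1, t2)."""
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    n = counts.size
    bins = (counts > t1).astype(int) + (counts > t2).astype(int)
    h = 0.0
    for b in range(3):
        sel = bins == b
        if sel.any():
            h += sel.sum() / n * _entropy(labels[sel])
    return h


def fit_thresholds(counts, labels) -> SeverityThresholds:
    """Exhaustive search over observed count values for the entropy-minimal
    (t1, t2) pair.

    Requires at least 3 samples spanning at least 2 distinct labels.
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels)
    if counts.size != labels.size:
        raise ValueError("counts and labels must have equal length")
    if counts.size < 3:
        raise ValueError(f"need at least 3 samples, got {counts.size}")
    if np.unique(labels).size < 2:
        raise ValueError("labels are degenerate (fewer than 2 distinct values)")
    values = np.unique(counts)
    candidates = np.unique(np.concatenate([[0], values]))
    best = None
    for i, t1 in enumerate(candidates):
        for t2 in candidates[i + 1 :]:
            h = conditional_entropy(counts, labels, int(t1), int(t2))
            key = (h, int(t1), int(t2))
            if best is None or key < best:
                best = key
    h, t1, t2 = best
    return SeverityThresholds(t1=t1, t2=t2, fitted_entropy=h)


def grade(count: int, thresholds: SeverityThresholds) -> str:
    """Map a lesion count to a severity class (monotone in the count)."""
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if count <= thresholds.t1:
        return thresholds.class_names[0]
    if count <= thresholds.t2:
        return thresholds.class_names[1]
    return thresholds.class_names[2]


def weighted_count(ma: int, he: int, ex: int, weights: dict | None = None) -> int:
    """Total lesion count with optional per-type weights (default: all 1).

    Keys: "MA", "HE", "EX"; the weighted sum is rounded to the nearest
    integer so it stays a valid grading count.
    """
    weights = weights or {}
    total = (
        weights.get("MA", 1.0) * ma
        + weights.get("HE", 1.0) * he
        + weights.get("EX", 1.0) * ex
    )
    return int(round(total))
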