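"""ROC / AUC / sensitivity / specificity for scored cohorts.

Written from first principles (threshold sweep over unique scores with
ties grouped, trapezoidal AUC) so the arithmetic is fully transparent;
tests cross-check it against a brute-force Mann–Whitney concordance
oracle and scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RocSummary",
    "OperatingPoint",
    "roc_curve",
    "evaluate_at",
    "youden_optimal",
    "concordance_auc",
    "validate_cohort",
]


class RocError(ValueError):
    """Raised when an ROC cannot be defined (e.g. single-class labels)."""


@dataclass(frozen=True)
class OperatingPoint:
    """Confusion counts and rates at one threshold (positive iff score >= t)."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass
class RocSummary:
    """A full threshold sweep: (FPR, TPR) points, AUC, operating point."""

    points: pd.DataFrame  # columns: threshold, fpr, tpr
    auc: float
    operating_point: OperatingPoint | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "auc": self.auc,
            "points": self.points.to_dict(orient="records"),
        }
        if self.operating_point is not None:
            payload["operating_point"] = self.operating_point.to_dict()
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def points_to_csv(self, path: str | Path) -> None:
        self.points.to_csv(path, index=False, columns=["fpr", "tpr", "threshold"])


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise RocError("scores and labels must be equal-length 1-D sequences")
    if not set(np.unique(y)) <= {0, 1}:
        raise RocError("labels must be binary 0/1")
    if y.min() == y.max():
        raise RocError("ROC undefined: only one class present in labels")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> RocSummary:
    """Threshold sweep over the unique scores, descending, ties grouped.

    The curve starts at (0, 0) (threshold above every score) and ends at
    (1, 1); AUC is the trapezoidal area under the resulting points.
    """
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # one point per unique score: cumulative TP/FP after each tie group
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx]]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return RocSummary(points=points, auc=auc)


def evaluate_at(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> OperatingPoint:
    """Confusion counts at a fixed threshold; positive iff score >= threshold."""
    s, y = _check(scores, labels)
    pred = s >= threshold
    return OperatingPoint(
        threshold=float(threshold),
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def youden_optimal(scores: Sequence[float], labels: Sequence[int]) -> OperatingPoint:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties on J are broken toward the higher threshold (fewer positives).
    """
    s, _ = _check(scores, labels)
    best: OperatingPoint | None = None
    for t in sorted(np.unique(s), reverse=True):
        op = evaluate_at(scores, labels, t)
        j = op.sensitivity + op.specificity - 1.0
        if best is None or j > best.sensitivity + best.specificity - 1.0:
            best = op
    assert best is not None
    return best


def concordance_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force Mann–Whitney concordance: the probability that a random
    case outscores a random control, counting ties as 1/2.

    O(n_pos * n_neg); independent oracle for :func:`roc_curve`'s AUC.
    """
    s, y = _check(scores, labels)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return float(wins / (len(pos) * len(neg)))


def validate_cohort(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float | None = None,
) -> RocSummary:
    """ROC sweep plus an operating point at ``threshold`` (or the
    Youden-optimal point when no threshold is given)."""
    summary = roc_curve(scores, labels)
    if threshold is not None:
        summary.operating_point = evaluate_at(scores, labels, threshold)
    else:
        summary.operating_point = youden_optimal(scores, labels)
    return summary
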