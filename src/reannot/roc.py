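"""Rating-based ROC evaluation of annotation sources.

Each evaluation case pairs a binary truth label (1 = truly positive,
0 = truly negative) with an ordinal confidence rating (the study coded
ratings 2–5). Sweeping the decision rule "predict positive iff rating >= t"
over the distinct ratings traces the empirical ROC curve; its trapezoidal
area equals the Mann–Whitney concordance statistic
(#concordant + ½·#tied) / (n₁·n₀), and is invariant under any strictly
increasing re-coding of the ratings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RatingCase",
    "EvalSummary",
    "roc_points",
    "empiric_auc",
    "summary_at_threshold",
    "mean_accuracy",
]


@dataclass(frozen=True)
class RatingCase:
    case_id: str
    truth: int
    rating: int

    def __post_init__(self) -> None:
        if self.truth not in (0, 1):
            raise ValueError(f"{self.case_id}: truth must be 0 or 1")


@dataclass(frozen=True)
class EvalSummary:
    source: str
    n_cases: int
    accuracy: float
    sensitivity: float
    specificity: float
    empiric_area: float
    operating_threshold: int


def _split(cases: Sequence[RatingCase]) -> tuple[list[int], list[int]]:
    pos = [c.rating for c in cases if c.truth == 1]
    neg = [c.rating for c in cases if c.truth == 0]
    if not pos or not neg:
        raise ValueError("ROC needs at least one positive and one negative case")
    return pos, neg


def roc_points(cases: Sequence[RatingCase]) -> list[tuple[float, float]]:
    """Empirical ROC points (FPR, TPR), from (0,0) to (1,1).

    One point per distinct rating threshold t with the rule
    "positive iff rating >= t", ordered by non-decreasing FPR.
    """
    pos, neg = _split(cases)
    n1, n0 = len(pos), len(neg)
    points = [(0.0, 0.0)]
    for t in sorted(set(pos + neg), reverse=True):
        tpr = sum(r >= t for r in pos) / n1
        fpr = sum(r >= t for r in neg) / n0
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def empiric_auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC point list."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    if np.any(np.diff(fpr) < 0):
        raise ValueError("FPR must be non-decreasing")
    return float(np.trapezoid(tpr, fpr))


def _confusion(cases: Sequence[RatingCase], t: int) -> tuple[int, int, int, int]:
    tp = sum(1 for c in cases if c.truth == 1 and c.rating >= t)
    fn = sum(1 for c in cases if c.truth == 1 and c.rating < t)
    tn = sum(1 for c in cases if c.truth == 0 and c.rating < t)
    fp = sum(1 for c in cases if c.truth == 0 and c.rating >= t)
    return tp, fn, tn, fp


def summary_at_threshold(
    cases: Sequence[RatingCase],
    t: int | None = None,
    source: str = "",
) -> EvalSummary:
    """Accuracy, sensitivity and specificity at an operating threshold.

    With ``t=None`` the threshold maximising Youden's J (sensitivity +
    specificity − 1) is used; ties go to the lower threshold.
    """
    pos, neg = _split(cases)
    ratings = sorted(set(pos + neg))
    if t is None:
        best_j, best_t = -np.inf, ratings[0]
        for cand in ratings:
            tp, fn, tn, fp = _confusion(cases, cand)
            j = tp / (tp + fn) + tn / (tn + fp) - 1.0
            if j > best_j:
                best_j, best_t = j, cand
        t = best_t
    tp, fn, tn, fp = _confusion(cases, t)
    n = len(cases)
    return EvalSummary(
        source=source,
        n_cases=n,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        empiric_area=empiric_auc(roc_points(cases)),
        operating_threshold=int(t),
    )


def mean_accuracy(summaries: Sequence[EvalSummary]) -> float:
    """Unweighted mean of per-source accuracies."""
    if not summaries:
        raise ValueError("no summaries to average")
    return float(np.mean([s.accuracy for s in summaries]))
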