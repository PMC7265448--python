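"""Validation of automated Defence Cascade measures against observers.

Three statistics compare an automated measure with the observer ground
truth over a corpus of tests: Spearman rank correlation (mid-ranks for
ties — the 0-4 observer score makes ties pervasive), a confusion analysis
of freeze *occurrence* (a test counts as "freeze" when its duration is
strictly positive), and the rank correlation restricted to true positives
(tests where both methods detected a freeze), which guards against
correlations driven purely by the many zero durations.

No p-values are reported for the correlations: tests are nested within
sessions within pigs, so naive p-values would be inaccurate; rho and n
are reported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ConfusionCounts", "ConfusionMetrics", "spearman_rho",
           "freeze_confusion", "confusion_metrics",
           "true_positive_correlation", "REFERENCE_FREEZE_CONFUSION"]


#: Published freeze-occurrence confusion counts (automated vs observer)
#: from the 280-test pig Defence Cascade validation study this pipeline
#: mirrors: measure -> (tp, fp, tn, fn).
REFERENCE_FREEZE_CONFUSION: dict[str, tuple[int, int, int, int]] = {
    "Kinect Acceleration": (114, 15, 122, 29),
    "Kinect Speed": (109, 11, 126, 34),
    "Load Platform": (84, 4, 133, 59),
    "KLT Acceleration": (79, 2, 135, 64),
    "KLT Speed": (102, 7, 130, 41),
}


@dataclass(frozen=True)
class ConfusionCounts:
    """Freeze-occurrence agreement counts, automated vs observer."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV; NaN where the denominator is 0."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Equivalent to the Pearson correlation of average-ranked values.
    Raises if either vector has zero rank variance (the correlation is
    undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero rank variance: correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def freeze_confusion(auto_durations: Sequence[float],
                     obs_durations: Sequence[float]) -> ConfusionCounts:
    """Tally freeze occurrence (duration > 0) of an automated measure
    against the observer."""
    a = np.asarray(auto_durations, dtype=float)
    o = np.asarray(obs_durations, dtype=float)
    if a.shape != o.shape:
        raise ValueError("length mismatch")
    if np.any(a < 0) or np.any(o < 0):
        raise ValueError("durations must be >= 0")
    af, of = a > 0, o > 0
    return ConfusionCounts(tp=int(np.sum(af & of)),
                           fp=int(np.sum(af & ~of)),
                           tn=int(np.sum(~af & ~of)),
                           fn=int(np.sum(~af & of)))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV and NPV of freeze occurrence.

    Metrics with a zero denominator are returned as NaN (undefined).
    Values round to 3 decimal places for comparison with published
    tables.
    """
    return ConfusionMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def true_positive_correlation(auto_durations: Sequence[float],
                              obs_durations: Sequence[float]
                              ) -> tuple[float, int]:
    """Spearman rho restricted to tests where both durations are > 0.

    Returns ``(rho, n_tp)``; raises when fewer than 3 true-positive pairs
    remain.
    """
    a = np.asarray(auto_durations, dtype=float)
    o = np.asarray(obs_durations, dtype=float)
    if a.shape != o.shape:
        raise ValueError("length mismatch")
    both = (a > 0) & (o > 0)
    n_tp = int(both.sum())
    if n_tp < 3:
        raise ValueError(f"only {n_tp} true-positive pairs; "
                         "correlation undefined")
    return spearman_rho(a[both], o[both]), n_tp
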