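"""Threshold-level confusion statistics, AUC, Youden threshold and the
gray-zone workload metrics.

Conventions
-----------
A case is *called positive* at threshold τ iff its score is ≥ τ (closed at
τ); the rule-out side uses the strict complement, score < τ. PPV(τ) is the
precision over positive calls, NPV(τ) the precision over negative calls;
either is *undefined* (returned as ``nan``) when its denominator is empty —
a vacuous reliability claim never opens a safe zone.

The Gray Zone Area

    Γ_Area = FPR(τ⁻) × (1 − TPR(τ⁺))

is the rectangle in ROC space spanned by the false-positive rate at the
rule-out boundary and the miss rate at the rule-in boundary; it is the
geometric cost of indecision. An empty rule-out zone contributes FPR = 1
and an empty rule-in zone contributes TPR = 0, so Γ_Area degrades to 1
when nothing is automatable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cohort import ScoredCohort
from .errors import UsageError

__all__ = [
    "ConfusionCounts",
    "OperatingPoint",
    "ThresholdTable",
    "confusion_at",
    "ppv_at",
    "npv_at",
    "roc_point_at",
    "auc",
    "youden_theta",
    "gray_area",
    "gray_fraction",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class OperatingPoint:
    tpr: float
    fpr: float


class ThresholdTable:
    """Confusion statistics at every candidate threshold of a cohort.

    Candidates are the ascending unique scores, prefixed by a ``-inf``
    sentinel (call everything positive / empty rule-out zone) and suffixed
    by ``+inf`` (call nothing positive / empty rule-in zone). Every
    achievable confusion table of the score ≥ τ rule is realized at one of
    the finite candidates; the sentinels realize the two degenerate tables.
    """

    def __init__(self, cohort: ScoredCohort):
        scores, labels = cohort.scores, cohort.labels
        uniq = np.unique(scores)
        self.candidates = np.concatenate(([-np.inf], uniq, [np.inf]))
        pos_sorted = np.sort(scores[labels == 1])
        neg_sorted = np.sort(scores[labels == 0])
        self.n_pos = len(pos_sorted)
        self.n_neg = len(neg_sorted)
        self.n = self.n_pos + self.n_neg
        # counts strictly below each candidate
        self.pos_below = np.searchsorted(pos_sorted, self.candidates, side="left")
        self.neg_below = np.searchsorted(neg_sorted, self.candidates, side="left")
        self.tp = self.n_pos - self.pos_below
        self.fp = self.n_neg - self.neg_below
        self.fn = self.pos_below
        self.tn = self.neg_below
        with np.errstate(invalid="ignore", divide="ignore"):
            self.ppv = np.where(self.tp + self.fp > 0,
                                self.tp / np.maximum(self.tp + self.fp, 1), np.nan)
            self.npv = np.where(self.tn + self.fn > 0,
                                self.tn / np.maximum(self.tn + self.fn, 1), np.nan)
            self.tpr = self.tp / self.n_pos if self.n_pos else np.full_like(self.ppv, np.nan)
            self.fpr = self.fp / self.n_neg if self.n_neg else np.full_like(self.ppv, np.nan)
        self.fingerprint = cohort.fingerprint


def _counts_at(cohort: ScoredCohort, tau: float) -> ConfusionCounts:
    pos = cohort.labels == 1
    called = cohort.scores >= tau
    tp = int(np.count_nonzero(called & pos))
    fp = int(np.count_nonzero(called & ~pos))
    fn = int(np.count_nonzero(~called & pos))
    tn = int(np.count_nonzero(~called & ~pos))
    return ConfusionCounts(tp, fp, tn, fn)


def confusion_at(cohort: ScoredCohort, tau: float) -> ConfusionCounts:
    """Confusion counts with the *score ≥ τ is a positive call* rule."""
    return _counts_at(cohort, tau)


def ppv_at(cohort: ScoredCohort, tau: float) -> float:
    """Precision over positive calls at τ; ``nan`` if there are none."""
    c = _counts_at(cohort, tau)
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else math.nan


def npv_at(cohort: ScoredCohort, tau: float) -> float:
    """Precision over negative calls (score < τ); ``nan`` if there are none."""
    c = _counts_at(cohort, tau)
    return c.tn / (c.tn + c.fn) if (c.tn + c.fn) else math.nan


def roc_point_at(cohort: ScoredCohort, tau: float) -> OperatingPoint:
    cohort.require_two_class()
    c = _counts_at(cohort, tau)
    return OperatingPoint(tpr=c.tp / (c.tp + c.fn), fpr=c.fp / (c.fp + c.tn))


def auc(cohort: ScoredCohort) -> float:
    """Probability a random positive outscores a random negative, ties ½.

    Computed as the Mann–Whitney rank statistic, which equals the
    trapezoidal area under the empirical ROC curve.
    """
    cohort.require_two_class()
    ranks = rankdata(cohort.scores)
    n_pos, n_neg = cohort.n_pos, cohort.n_neg
    rank_sum = ranks[cohort.labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def youden_theta(cohort: ScoredCohort) -> float:
    """Threshold maximizing Youden's J = TPR − FPR.

    Ties are broken toward the higher TPR, then the lower threshold
    (favoring sensitivity). The scan covers the unique scores and the
    above-max sentinel; the call-everything point is not a distinct
    operating point from the lowest score and is skipped.
    """
    cohort.require_two_class()
    t = ThresholdTable(cohort)
    cand, tpr, fpr = t.candidates[1:], t.tpr[1:], t.fpr[1:]
    j = tpr - fpr
    # lexicographic argmax of (J, TPR, -tau)
    order = np.lexsort((cand, -tpr, -j))
    return float(cand[order[0]])


def gray_area(cohort: ScoredCohort, boundaries) -> float:
    """Γ_Area = FPR(τ⁻) × (1 − TPR(τ⁺)) from the raw safe-zone boundaries.

    ``boundaries`` must have been derived from this cohort (fingerprint
    checked).
    """
    if getattr(boundaries, "cohort_fingerprint", None) != cohort.fingerprint:
        raise UsageError("boundaries were not derived from this cohort")
    cohort.require_two_class()
    tau_minus = boundaries.tau_minus_raw
    tau_plus = boundaries.tau_plus_raw
    fpr = float(np.count_nonzero(cohort.scores[cohort.labels == 0] >= tau_minus)) / cohort.n_neg
    tpr = float(np.count_nonzero(cohort.scores[cohort.labels == 1] >= tau_plus)) / cohort.n_pos
    return fpr * (1.0 - tpr)


def gray_fraction(partition) -> float:
    """Fraction of the cohort deferred to the gray zone."""
    assignment = np.asarray(partition.assignment)
    return float(np.count_nonzero(assignment == "GRAY")) / len(assignment)
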