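"""Uncertainty quantification and comparative analytics.

* Percentile bootstrap confidence intervals (2.5th/97.5th percentiles of the
  statistic over B with-replacement resamples; zone boundaries re-derived
  inside every replicate unless explicitly frozen).
* Prevalence-shift simulation: the complete negative set is held fixed and
  positives are resampled with replacement to hit a target prevalence.
* Paired two-model comparison of rule-out capacity on identical cases.
* Cross-model zone concordance and human-reader stratification by zone.

RNG recipe
----------
Every stochastic operation draws from a single ``numpy.random.default_rng(seed)``
stream. A bootstrap replicate is ``rng.integers(0, n, n)`` (case indices with
replacement); a replicate that loses one class entirely is discarded and
redrawn from the same stream (the redraw count is reported), so exactly B
effective replicates enter each interval. Results are bit-reproducible from
``seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ScoredCohort, ReaderOutcome
from .errors import CohortValidationError, NumericError, UsageError
from .metrics import auc, gray_area
from .zones import (
    SafetyPolicy,
    ZonePartition,
    ZONE_GRAY,
    ZONE_RULE_IN,
    ZONE_RULE_OUT,
    make_partition,
    rule_in_boundary,
    rule_out_boundary,
)

__all__ = [
    "IntervalEstimate",
    "PrevalenceScenario",
    "bootstrap_interval",
    "prevalence_sweep",
    "paired_model_difference",
    "zone_concordance",
    "stratify_reader_outcomes",
]

logger = logging.getLogger(__name__)

_STATISTICS = ("auc", "gamma_area", "gray_fraction", "rule_out_tn_count")


@dataclass
class IntervalEstimate:
    """Percentile-bootstrap interval for one statistic."""

    statistic_name: str
    point: float
    lower: float
    upper: float
    B: int
    seed: int
    n_redrawn: int = 0

    def to_record(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "B": self.B,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
        }


@dataclass
class PrevalenceScenario:
    """Zone metrics at one target prevalence (fixed negatives, resampled
    positives)."""

    target_prevalence: float
    n_negatives_fixed: int
    n_positives_target: int
    replicates: pd.DataFrame = field(repr=False)
    summary: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "target_prevalence": self.target_prevalence,
            "n_negatives_fixed": self.n_negatives_fixed,
            "n_positives_target": self.n_positives_target,
            "summary": self.summary,
        }


def _make_stat_fn(statistic: str, alpha: float | None, freeze_from: ScoredCohort | None):
    """Statistic evaluator over a (possibly resampled) cohort."""
    if statistic not in _STATISTICS:
        raise UsageError(f"unknown statistic {statistic!r}; one of {_STATISTICS}")
    if statistic != "auc" and alpha is None:
        raise UsageError(f"statistic {statistic!r} requires alpha")

    frozen = None
    if freeze_from is not None and statistic != "auc":
        frozen = make_partition(freeze_from, SafetyPolicy.symmetric(alpha)).boundaries

    def fn(cohort: ScoredCohort) -> float:
        if statistic == "auc":
            return auc(cohort)
        if frozen is not None:
            tau_minus, tau_plus = frozen.tau_minus, frozen.tau_plus
            tm_raw, tp_raw = frozen.tau_minus_raw, frozen.tau_plus_raw
        else:
            part = make_partition(cohort, SafetyPolicy.symmetric(alpha))
            b = part.boundaries
            tau_minus, tau_plus = b.tau_minus, b.tau_plus
            tm_raw, tp_raw = b.tau_minus_raw, b.tau_plus_raw
        s, y = cohort.scores, cohort.labels
        if statistic == "gamma_area":
            n_neg = (y == 0).sum()
            n_pos = (y == 1).sum()
            fpr = np.count_nonzero(s[y == 0] >= tm_raw) / n_neg
            tpr = np.count_nonzero(s[y == 1] >= tp_raw) / n_pos
            return float(fpr * (1.0 - tpr))
        if statistic == "gray_fraction":
            return float(np.count_nonzero((s >= tau_minus) & (s < tau_plus)) / len(s))
        # rule_out_tn_count: true negatives confidently ruled out at α⁻
        if frozen is not None:
            tau = tm_raw
        else:
            tau = rule_out_boundary(cohort, alpha)
        return float(np.count_nonzero((s < tau) & (y == 0)))

    return fn


def _resample_indices(rng, n, labels, max_extra):
    """One with-replacement resample keeping both classes; returns
    (indices, n_redrawn)."""
    redrawn = 0
    while True:
        idx = rng.integers(0, n, n)
        sub = labels[idx]
        if 0 < sub.sum() < n:
            return idx, redrawn
        redrawn += 1
        if redrawn > max_extra:
            raise NumericError(
                "bootstrap resamples lose a class more often than not; "
                "cohort too small or too imbalanced"
            )


def bootstrap_interval(
    cohort: ScoredCohort,
    statistic: str,
    B: int = 2000,
    seed: int = 0,
    alpha: float | None = None,
    freeze_boundaries: bool = False,
) -> IntervalEstimate:
    """Percentile bootstrap CI for one statistic.

    ``statistic`` is one of ``auc``, ``gamma_area``, ``gray_fraction``
    (symmetric safety level ``alpha``) or ``rule_out_tn_count`` (rule-out
    level ``alpha``). Boundaries are re-derived within each replicate
    unless ``freeze_boundaries``.
    """
    if B < 2:
        raise UsageError("B must be >= 2")
    cohort.require_two_class()
    fn = _make_stat_fn(statistic, alpha, cohort if freeze_boundaries else None)
    point = fn(cohort)
    rng = np.random.default_rng(seed)
    n = cohort.n
    values = np.empty(B)
    total_redrawn = 0
    labels = cohort.labels.astype(np.int64)
    for b in range(B):
        idx, redrawn = _resample_indices(rng, n, labels, max_extra=10 * B)
        total_redrawn += redrawn
        values[b] = fn(cohort.subset(idx))
    if total_redrawn:
        logger.info("bootstrap: %d single-class resamples redrawn", total_redrawn)
    valid = values[~np.isnan(values)]
    if len(valid) < B / 2:
        raise NumericError(
            f"statistic {statistic!r} undefined on {B - len(valid)}/{B} resamples"
        )
    lower, upper = np.percentile(valid, [2.5, 97.5])
    name = statistic if alpha is None else f"{statistic}@{alpha:g}"
    return IntervalEstimate(name, float(point), float(lower), float(upper),
                            B=B, seed=seed, n_redrawn=total_redrawn)


def target_positive_count(n_neg: int, prevalence: float) -> int:
    """Positives needed so that n_pos/(n_pos+n_neg) ≈ prevalence
    (round-half-to-even)."""
    if not (0.0 < prevalence < 1.0):
        raise UsageError(f"prevalence must lie in (0, 1), got {prevalence}")
    return int(np.rint(n_neg * prevalence / (1.0 - prevalence)))


def prevalence_sweep(
    cohort: ScoredCohort,
    prevalences,
    alpha_minus: float,
    B: int = 200,
    seed: int = 0,
) -> list[PrevalenceScenario]:
    """Zone metrics under prevalence shift.

    For each target prevalence, B synthetic cohorts are built that contain
    the complete negative set exactly once plus positives resampled with
    replacement to the rounded target count; the rule-out boundary, zone
    sizes and Γ_Area (symmetric level = ``alpha_minus``) are recomputed per
    replicate and summarized with 2.5/97.5 percentile intervals.
    """
    cohort.require_two_class()
    rng = np.random.default_rng(seed)
    neg_idx = np.where(cohort.labels == 0)[0]
    pos_idx = np.where(cohort.labels == 1)[0]
    scenarios = []
    for p in prevalences:
        k = target_positive_count(len(neg_idx), p)
        if k == 0:
            raise UsageError(
                f"target prevalence {p} yields zero positives with "
                f"{len(neg_idx)} negatives"
            )
        rows = []
        for b in range(B):
            draw = rng.choice(pos_idx, size=k, replace=True)
            idx = np.concatenate((neg_idx, draw))
            sub = cohort.subset(idx)
            part = make_partition(sub, SafetyPolicy.symmetric(alpha_minus))
            zc = part.zone_counts
            rows.append(
                {
                    "replicate": b,
                    "tau_minus": part.boundaries.tau_minus,
                    "n_rule_out": zc[ZONE_RULE_OUT],
                    "n_rule_in": zc[ZONE_RULE_IN],
                    "n_gray": zc[ZONE_GRAY],
                    "rule_out_tn": int(
                        np.count_nonzero(
                            (sub.scores < part.boundaries.tau_minus) & (sub.labels == 0)
                        )
                    ),
                    "gamma_area": gray_area(sub, part.boundaries),
                    "gray_fraction": zc[ZONE_GRAY] / sub.n,
                    "realized_prevalence": sub.prevalence,
                }
            )
        df = pd.DataFrame(rows)
        summary = {}
        for col in ("n_rule_out", "rule_out_tn", "gamma_area", "gray_fraction"):
            lo, hi = np.percentile(df[col], [2.5, 97.5])
            summary[col] = {"mean": float(df[col].mean()), "lower": float(lo),
                            "upper": float(hi)}
        scenarios.append(
            PrevalenceScenario(
                target_prevalence=float(p),
                n_negatives_fixed=len(neg_idx),
                n_positives_target=k,
                replicates=df,
                summary=summary,
            )
        )
    return scenarios


def _check_paired(a: ScoredCohort, b: ScoredCohort) -> np.ndarray:
    """Validate identical case sets/labels; return b-indices aligned to a."""
    if a.n != b.n:
        raise CohortValidationError("cohorts differ in size")
    order_b = {cid: k for k, cid in enumerate(b.case_ids)}
    try:
        align = np.array([order_b[cid] for cid in a.case_ids])
    except KeyError as exc:
        raise CohortValidationError(f"case_id {exc.args[0]!r} missing in second cohort")
    if not (a.labels == b.labels[align]).all():
        raise CohortValidationError("labels disagree between paired cohorts")
    return align


def paired_model_difference(
    cohort_a: ScoredCohort,
    cohort_b: ScoredCohort,
    alpha_minus: float,
    B: int = 2000,
    seed: int = 0,
) -> IntervalEstimate:
    """Rule-out capacity difference (model B − model A) with a paired
    case-level bootstrap.

    The statistic is the number of true negatives inside the rule-out safe
    zone at ``alpha_minus`` under model B minus the same count under model
    A; both boundaries are re-derived per replicate on the same resampled
    cases.
    """
    align = _check_paired(cohort_a, cohort_b)
    sb = cohort_b.scores[align]
    labels = cohort_a.labels
    sa = cohort_a.scores

    def stat(idx) -> float:
        ca = ScoredCohort(cohort_a.case_ids[idx], sa[idx], labels[idx], validate=False)
        cb = ScoredCohort(cohort_a.case_ids[idx], sb[idx], labels[idx], validate=False)
        ta = rule_out_boundary(ca, alpha_minus)
        tb = rule_out_boundary(cb, alpha_minus)
        na = np.count_nonzero((sa[idx] < ta) & (labels[idx] == 0))
        nb = np.count_nonzero((sb[idx] < tb) & (labels[idx] == 0))
        return float(nb - na)

    full = np.arange(cohort_a.n)
    point = stat(full)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    total_redrawn = 0
    lab64 = labels.astype(np.int64)
    for b in range(B):
        idx, redrawn = _resample_indices(rng, cohort_a.n, lab64, max_extra=10 * B)
        total_redrawn += redrawn
        values[b] = stat(idx)
    lower, upper = np.percentile(values, [2.5, 97.5])
    return IntervalEstimate(
        f"rule_out_tn_diff@{alpha_minus:g}", point, float(lower), float(upper),
        B=B, seed=seed, n_redrawn=total_redrawn,
    )


def zone_concordance(partition_a: ZonePartition, partition_b: ZonePartition) -> pd.DataFrame:
    """3×3 contingency of zone assignments across two partitions of the
    same cases (rows: model A zones, columns: model B zones)."""
    ids_a, ids_b = partition_a.cohort.case_ids, partition_b.cohort.case_ids
    order_b = {cid: k for k, cid in enumerate(ids_b)}
    try:
        align = np.array([order_b[cid] for cid in ids_a])
    except KeyError as exc:
        raise CohortValidationError(f"case_id {exc.args[0]!r} missing in second partition")
    zones = (ZONE_RULE_OUT, ZONE_GRAY, ZONE_RULE_IN)
    za = partition_a.assignment
    zb = partition_b.assignment[align]
    mat = pd.DataFrame(0, index=list(zones), columns=list(zones))
    for a in zones:
        for b in zones:
            mat.loc[a, b] = int(np.count_nonzero((za == a) & (zb == b)))
    return mat


def stratify_reader_outcomes(cohort: ScoredCohort, zone_specs=None) -> pd.DataFrame:
    """Human-reader outcome mix within AI safe zones.

    ``zone_specs`` is a list of ``(kind, alpha)`` with kind in
    ``{"rule_in", "rule_out", "gray"}``; each zone is computed independently
    at its level (nested zones appear as separate rows). Cases without a
    reader call are excluded (count logged). Default: rule-out and rule-in
    at α ∈ {1.0, 0.95, 0.90} plus the gray zone at α = 0.90.
    """
    if not cohort.has_reader_calls:
        raise CohortValidationError("cohort has no reader calls")
    if zone_specs is None:
        zone_specs = (
            [("rule_out", a) for a in (1.0, 0.95, 0.90)]
            + [("gray", 0.90)]
            + [("rule_in", a) for a in (1.0, 0.95, 0.90)]
        )
    has_call = ~np.isnan(cohort.reader_calls)
    n_missing = int((~has_call).sum())
    if n_missing:
        logger.info("reader stratification: %d cases lack a reader call", n_missing)
    outcome = np.full(cohort.n, "", dtype=object)
    for k in np.where(has_call)[0]:
        outcome[k] = ReaderOutcome.from_call(
            int(cohort.reader_calls[k]), int(cohort.labels[k])
        ).value

    rows = []
    for kind, a in zone_specs:
        if kind == "rule_in":
            mask = cohort.scores >= rule_in_boundary(cohort, a)
        elif kind == "rule_out":
            mask = cohort.scores < rule_out_boundary(cohort, a)
        elif kind == "gray":
            part = make_partition(cohort, SafetyPolicy.symmetric(a))
            mask = part.assignment == ZONE_GRAY
        else:
            raise UsageError(f"unknown zone kind {kind!r}")
        mask = mask & has_call
        size = int(mask.sum())
        counts = {o: int(np.count_nonzero(outcome[mask] == o)) for o in
                  ("TP", "TN", "FP", "FN")}
        acc = (counts["TP"] + counts["TN"]) / size if size else float("nan")
        row = {"zone": kind, "alpha": a, "size": size, "accuracy": acc}
        for o, c in counts.items():
            row[f"n_{o.lower()}"] = c
            row[f"prop_{o.lower()}"] = c / size if size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
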