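"""Safe-zone boundary search and three-zone partition.

A safety policy states two reliability targets: the minimum acceptable PPV
for an autonomous rule-in call (α⁺) and the minimum acceptable NPV for an
autonomous rule-out call (α⁻). The score range is then split into

* the **Rule-in Safe Zone** {s ≥ τ⁺}, where escalation is trusted,
* the **Rule-out Safe Zone** {s < τ⁻}, where de-prioritization is trusted,
* the **Gray Zone** in between, mandating human review.

Boundary search
---------------
The *raw* boundaries follow the literal set definitions: τ⁺ is the infimum
of all candidate thresholds whose PPV meets α⁺, τ⁻ the supremum of those
whose NPV meets α⁻. Candidates are the finite grid of unique scores plus
two sentinels, so both bounds are attained and the boundary-threshold
PPV/NPV is guaranteed ≥ its target. Thresholds with an undefined (empty
denominator) PPV/NPV never qualify.

Under lenient targets the two raw boundaries can cross (τ⁻ > τ⁺). The
partition then resolves the overlap by choosing, among all *qualifying*
boundary pairs (τ⁻ at a candidate meeting α⁻ or the empty sentinel, τ⁺ at
a candidate meeting α⁺ or the empty sentinel, τ⁻ ≤ τ⁺), the pair leaving
the fewest cases in the gray zone, tie-broken toward the larger rule-in
zone and then the larger rule-out zone. This rule coincides exactly with
the raw boundaries whenever they do not cross, keeps the zone-level
PPV/NPV guarantee in force for every nonempty zone, and makes the gray
fraction non-decreasing in the symmetric safety level by construction
(qualifying sets only shrink as α grows). Crossed raw boundaries are
reported via the ``clipped`` flag.

Γ_Area is always computed from the raw boundaries (the ROC rectangle of
the two independent reliability searches), which keeps it non-decreasing
in the symmetric safety level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ScoredCohort
from .errors import UsageError
from .metrics import ThresholdTable, gray_area

__all__ = [
    "EMPTY_RULE_IN",
    "EMPTY_RULE_OUT",
    "DEFAULT_ALPHA_GRID",
    "SafetyPolicy",
    "ZoneBoundaries",
    "ZonePartition",
    "SafetyProfile",
    "candidate_thresholds",
    "rule_in_boundary",
    "rule_out_boundary",
    "make_partition",
    "safety_profile",
]

logger = logging.getLogger(__name__)

#: Sentinel meaning "no threshold qualifies for rule-in": behaves as a
#: threshold above every score, so the rule-in zone is empty and TPR = 0.
EMPTY_RULE_IN = float("inf")
#: Sentinel meaning "no threshold qualifies for rule-out": behaves as a
#: threshold at/below every score, so the rule-out zone is empty and FPR = 1.
EMPTY_RULE_OUT = float("-inf")

#: Default safety-level grid for profiles: 0.50 … 1.00 in steps of 0.005.
DEFAULT_ALPHA_GRID = np.round(np.arange(0.50, 1.0 + 1e-9, 0.005), 6)

ZONE_RULE_IN = "RULE_IN"
ZONE_RULE_OUT = "RULE_OUT"
ZONE_GRAY = "GRAY"


@dataclass(frozen=True)
class SafetyPolicy:
    """Reliability targets: α⁺ (min PPV for rule-in), α⁻ (min NPV for
    rule-out); both in (0, 1]. A symmetric policy has α⁺ = α⁻."""

    alpha_plus: float
    alpha_minus: float

    def __post_init__(self):
        for name, v in (("alpha_plus", self.alpha_plus), ("alpha_minus", self.alpha_minus)):
            if not (0.0 < v <= 1.0):
                raise UsageError(f"{name} must lie in (0, 1], got {v}")

    @classmethod
    def symmetric(cls, alpha: float) -> "SafetyPolicy":
        return cls(alpha, alpha)


@dataclass(frozen=True)
class ZoneBoundaries:
    """Safe-zone boundaries for one cohort and policy.

    ``tau_plus``/``tau_minus`` are the effective (partition) boundaries;
    ``tau_plus_raw``/``tau_minus_raw`` the literal inf/sup search results
    (identical unless ``clipped``). ``EMPTY_RULE_IN``/``EMPTY_RULE_OUT``
    sentinels denote empty zones.
    """

    tau_plus: float
    tau_minus: float
    tau_plus_raw: float
    tau_minus_raw: float
    clipped: bool
    cohort_fingerprint: str

    @property
    def rule_in_empty(self) -> bool:
        return self.tau_plus == EMPTY_RULE_IN

    @property
    def rule_out_empty(self) -> bool:
        return self.tau_minus == EMPTY_RULE_OUT

    def to_record(self) -> dict:
        return {
            "tau_plus": self.tau_plus,
            "tau_minus": self.tau_minus,
            "tau_plus_raw": self.tau_plus_raw,
            "tau_minus_raw": self.tau_minus_raw,
            "clipped": self.clipped,
            "cohort_fingerprint": self.cohort_fingerprint,
        }


@dataclass
class ZonePartition:
    """Per-case zone assignment plus the boundaries that induced it."""

    boundaries: ZoneBoundaries
    assignment: np.ndarray  # of {"RULE_IN", "RULE_OUT", "GRAY"}
    policy: SafetyPolicy
    cohort: ScoredCohort = field(repr=False)

    @property
    def zone_counts(self) -> dict:
        vals, counts = np.unique(self.assignment, return_counts=True)
        out = {ZONE_RULE_IN: 0, ZONE_RULE_OUT: 0, ZONE_GRAY: 0}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out

    def achieved_alpha_plus(self) -> float:
        """PPV over the rule-in zone (nan if empty)."""
        mask = self.assignment == ZONE_RULE_IN
        return float((self.cohort.labels[mask] == 1).mean()) if mask.any() else float("nan")

    def achieved_alpha_minus(self) -> float:
        """NPV over the rule-out zone (nan if empty)."""
        mask = self.assignment == ZONE_RULE_OUT
        return float((self.cohort.labels[mask] == 0).mean()) if mask.any() else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.cohort.case_ids,
                "score": self.cohort.scores,
                "label": self.cohort.labels,
                "zone": self.assignment,
            }
        )


@dataclass
class SafetyProfile:
    """Gray-zone workload as a function of the safety level."""

    mode: str
    rows: pd.DataFrame  # columns: alpha, gray_fraction, gamma_area, tau_minus, tau_plus

    def to_dataframe(self) -> pd.DataFrame:
        return self.rows

    def to_record(self) -> dict:
        return {"mode": self.mode, "rows": self.rows.to_dict(orient="records")}


# ---------------------------------------------------------------------------
# searches

def candidate_thresholds(cohort: ScoredCohort) -> np.ndarray:
    """Ascending unique scores bracketed by the two sentinels."""
    return ThresholdTable(cohort).candidates


def _qualifying(table: ThresholdTable, alpha_plus=None, alpha_minus=None):
    qp = qm = None
    if alpha_plus is not None:
        qp = np.where(~np.isnan(table.ppv) & (table.ppv >= alpha_plus))[0]
    if alpha_minus is not None:
        qm = np.where(~np.isnan(table.npv) & (table.npv >= alpha_minus))[0]
    return qp, qm


def rule_in_boundary(cohort: ScoredCohort, alpha_plus: float) -> float:
    """Infimum candidate threshold with defined PPV ≥ α⁺ (``EMPTY_RULE_IN``
    if none qualifies)."""
    SafetyPolicy(alpha_plus, alpha_plus)  # range check
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    qp, _ = _qualifying(table, alpha_plus=alpha_plus)
    return float(table.candidates[qp[0]]) if len(qp) else EMPTY_RULE_IN


def rule_out_boundary(cohort: ScoredCohort, alpha_minus: float) -> float:
    """Supremum candidate threshold with defined NPV ≥ α⁻ (``EMPTY_RULE_OUT``
    if none qualifies)."""
    SafetyPolicy(alpha_minus, alpha_minus)
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    _, qm = _qualifying(table, alpha_minus=alpha_minus)
    return float(table.candidates[qm[-1]]) if len(qm) else EMPTY_RULE_OUT


def _search_boundaries(table: ThresholdTable, policy: SafetyPolicy):
    """Raw inf/sup boundaries plus the min-gray qualifying effective pair.

    Returns (tau_minus_eff, tau_plus_eff, tau_minus_raw, tau_plus_raw).
    """
    m = len(table.candidates)
    qp, qm = _qualifying(table, policy.alpha_plus, policy.alpha_minus)
    tau_plus_raw = float(table.candidates[qp[0]]) if len(qp) else EMPTY_RULE_IN
    tau_minus_raw = float(table.candidates[qm[-1]]) if len(qm) else EMPTY_RULE_OUT
    if tau_minus_raw <= tau_plus_raw:
        return tau_minus_raw, tau_plus_raw, tau_minus_raw, tau_plus_raw

    # overlap: min-gray qualifying pair. Index 0 is the -inf sentinel (empty
    # rule-out), index m-1 the +inf sentinel (empty rule-in); both always
    # admissible. below[k] = number of cases with score < candidate k.
    below = table.pos_below + table.neg_below
    I = np.unique(np.concatenate(([0], qm)))
    J = np.unique(np.concatenate((qp, [m - 1])))
    # for each admissible j, the best i is the largest admissible i ≤ j
    # (below[] is non-decreasing, so it maximizes the rule-out zone and
    # minimizes the gray count simultaneously)
    pos = np.searchsorted(I, J, side="right") - 1
    i_best = I[pos]
    gray = below[J] - below[i_best]
    k = np.lexsort((J, gray))[0]
    return (
        float(table.candidates[i_best[k]]),
        float(table.candidates[J[k]]),
        tau_minus_raw,
        tau_plus_raw,
    )


def make_partition(cohort: ScoredCohort, policy: SafetyPolicy) -> ZonePartition:
    """Partition the cohort into rule-in / gray / rule-out zones."""
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    tm, tp, tm_raw, tp_raw = _search_boundaries(table, policy)
    clipped = tm_raw > tp_raw
    if clipped:
        logger.warning(
            "safe-zone boundaries overlap (tau_minus=%g > tau_plus=%g); "
            "resolved to the minimal-gray qualifying pair (%g, %g)",
            tm_raw, tp_raw, tm, tp,
        )
    boundaries = ZoneBoundaries(
        tau_plus=tp,
        tau_minus=tm,
        tau_plus_raw=tp_raw,
        tau_minus_raw=tm_raw,
        clipped=clipped,
        cohort_fingerprint=cohort.fingerprint,
    )
    assignment = np.full(cohort.n, ZONE_GRAY, dtype=object)
    assignment[cohort.scores >= tp] = ZONE_RULE_IN
    assignment[cohort.scores < tm] = ZONE_RULE_OUT
    return ZonePartition(boundaries=boundaries, assignment=assignment,
                         policy=policy, cohort=cohort)


def safety_profile(
    cohort: ScoredCohort,
    alpha_grid=None,
    mode: str = "symmetric",
    fixed_alpha: float | None = None,
) -> SafetyProfile:
    """Gray-zone fraction and Γ_Area across a grid of safety levels.

    ``mode`` is ``"symmetric"`` (α⁺ = α⁻ = α), ``"fixed_alpha_minus"``
    (α⁻ = ``fixed_alpha``, grid varies α⁺) or ``"fixed_alpha_plus"``.
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise UsageError("alpha grid is empty")
    if mode not in ("symmetric", "fixed_alpha_minus", "fixed_alpha_plus"):
        raise UsageError(f"unknown profile mode {mode!r}")
    if mode != "symmetric" and fixed_alpha is None:
        raise UsageError(f"mode {mode!r} requires fixed_alpha")
    cohort.require_two_class()
    alpha_grid = np.sort(alpha_grid)
    rows = []
    for a in alpha_grid:
        if mode == "symmetric":
            policy = SafetyPolicy(a, a)
        elif mode == "fixed_alpha_minus":
            policy = SafetyPolicy(a, fixed_alpha)
        else:
            policy = SafetyPolicy(fixed_alpha, a)
        part = make_partition(cohort, policy)
        rows.append(
            {
                "alpha": float(a),
                "gray_fraction": float(np.count_nonzero(part.assignment == ZONE_GRAY))
                / cohort.n,
                "gamma_area": gray_area(cohort, part.boundaries),
                "tau_minus": part.boundaries.tau_minus,
                "tau_plus": part.boundaries.tau_plus,
            }
        )
    return SafetyProfile(mode=mode, rows=pd.DataFrame(rows))
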