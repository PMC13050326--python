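"""Operating-policy derivation: constraint pathways and utility maximization.

Two governance paradigms translate clinical priorities into a resolved
operating policy — a boundary pair (τ⁻, τ⁺) with achieved reliabilities and
zone counts:

* **Constraint pathways** fix exactly two of {rule-in reliability α⁺,
  rule-out reliability α⁻, gray-zone workload budget p_g}; the framework
  optimizes the third.

  - Pathway A (α⁺, α⁻ given): partition per the zone searches; report the
    resulting workload p_g.
  - Pathway B (α⁺, p_g_max given): fix τ⁺ from α⁺, then choose τ⁻ ≤ τ⁺
    maximizing the achieved rule-out reliability NPV(τ⁻) subject to the
    gray fraction not exceeding p_g_max; ties go to the larger rule-out
    zone. The attained NPV *is* the best achievable α⁻ by discreteness.
  - Pathway C (α⁻, p_g_max given): symmetric, maximizing achieved PPV(τ⁺).

  An infeasible budget yields a policy with the offending zone empty and
  ``feasible=False``, never an exception.

* **Utility maximization** assigns a per-case utility to each of the five
  outcomes (TP, TN, FP, FN, gray-zone deferral) and finds the exact argmax
  over all candidate threshold pairs τ⁻ ≤ τ⁺ of

      U_Total = n_TP·U_TP + n_TN·U_TN + n_FP·U_FP + n_FN·U_FN + n_Gray·U_Gray.

  Because U_Total separates into a τ⁻ term and a τ⁺ term over prefix
  counts, the argmax is found in O(m log m); ties are broken by fewest
  errors (n_FP + n_FN), then fewest deferrals, then the lexicographically
  smallest (τ⁻, τ⁺).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ScoredCohort
from .errors import UsageError
from .metrics import ThresholdTable
from .zones import (
    SafetyPolicy,
    ZoneBoundaries,
    ZONE_RULE_IN,
    ZONE_RULE_OUT,
    ZONE_GRAY,
    make_partition,
)

__all__ = [
    "UtilitySpec",
    "OperatingPolicy",
    "solve_constraints",
    "maximize_utility",
    "enumerate_policies",
]


@dataclass(frozen=True)
class UtilitySpec:
    """Per-case utilities for the five case outcomes (penalties negative)."""

    u_tp: float
    u_tn: float
    u_fp: float
    u_fn: float
    u_gray: float

    def __post_init__(self):
        for name in ("u_tp", "u_tn", "u_fp", "u_fn", "u_gray"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise UsageError(f"{name} must be finite, got {v}")

    def as_tuple(self):
        return (self.u_tp, self.u_tn, self.u_fp, self.u_fn, self.u_gray)


@dataclass
class OperatingPolicy:
    """A resolved policy: boundaries, achieved reliabilities, zone counts."""

    boundaries: ZoneBoundaries
    achieved_alpha_plus: float  # nan when the rule-in zone is empty
    achieved_alpha_minus: float  # nan when the rule-out zone is empty
    counts: dict  # n_tp, n_tn, n_fp, n_fn, n_gray
    gray_fraction: float
    pathway: str  # "A" | "B" | "C" | "U"
    feasible: bool = True
    total_utility: Optional[float] = None
    utility_table: Optional[pd.DataFrame] = None

    def to_record(self) -> dict:
        rec = {
            "pathway": self.pathway,
            "boundaries": self.boundaries.to_record(),
            "achieved_alpha_plus": self.achieved_alpha_plus,
            "achieved_alpha_minus": self.achieved_alpha_minus,
            "counts": self.counts,
            "gray_fraction": self.gray_fraction,
            "feasible": self.feasible,
        }
        if self.total_utility is not None:
            rec["total_utility"] = self.total_utility
        if self.utility_table is not None:
            rec["utility_table"] = self.utility_table.to_dict(orient="records")
        return rec


def _counts_for_pair(table: ThresholdTable, i: int, j: int) -> dict:
    """Outcome counts for boundary pair at candidate indices (i = τ⁻, j = τ⁺)."""
    n_fn = int(table.pos_below[i])
    n_tn = int(table.neg_below[i])
    n_tp = int(table.n_pos - table.pos_below[j])
    n_fp = int(table.n_neg - table.neg_below[j])
    n_gray = table.n - n_fn - n_tn - n_tp - n_fp
    return {"n_tp": n_tp, "n_tn": n_tn, "n_fp": n_fp, "n_fn": n_fn, "n_gray": n_gray}


def _policy_from_pair(cohort, table, i, j, pathway, feasible=True,
                      raw=None) -> OperatingPolicy:
    counts = _counts_for_pair(table, i, j)
    tau_minus = float(table.candidates[i])
    tau_plus = float(table.candidates[j])
    raw = raw or (tau_minus, tau_plus)
    boundaries = ZoneBoundaries(
        tau_plus=tau_plus,
        tau_minus=tau_minus,
        tau_plus_raw=raw[1],
        tau_minus_raw=raw[0],
        clipped=False,
        cohort_fingerprint=cohort.fingerprint,
    )
    app = counts["n_tp"] / (counts["n_tp"] + counts["n_fp"]) \
        if counts["n_tp"] + counts["n_fp"] else float("nan")
    apm = counts["n_tn"] / (counts["n_tn"] + counts["n_fn"]) \
        if counts["n_tn"] + counts["n_fn"] else float("nan")
    return OperatingPolicy(
        boundaries=boundaries,
        achieved_alpha_plus=app,
        achieved_alpha_minus=apm,
        counts=counts,
        gray_fraction=counts["n_gray"] / table.n,
        pathway=pathway,
        feasible=feasible,
    )


def solve_constraints(
    cohort: ScoredCohort,
    alpha_plus: float | None = None,
    alpha_minus: float | None = None,
    p_g_max: float | None = None,
) -> OperatingPolicy:
    """Resolve a policy from exactly two of {α⁺, α⁻, p_g_max}."""
    given = [x is not None for x in (alpha_plus, alpha_minus, p_g_max)]
    if sum(given) != 2:
        raise UsageError(
            "exactly two of alpha_plus, alpha_minus, p_g_max must be given"
        )
    if p_g_max is not None and not (0.0 <= p_g_max <= 1.0):
        raise UsageError(f"p_g_max must lie in [0, 1], got {p_g_max}")
    cohort.require_two_class()

    if p_g_max is None:  # Pathway A
        policy = SafetyPolicy(alpha_plus, alpha_minus)
        part = make_partition(cohort, policy)
        table = ThresholdTable(cohort)
        zc = part.zone_counts
        mask_in = part.assignment == ZONE_RULE_IN
        mask_out = part.assignment == ZONE_RULE_OUT
        counts = {
            "n_tp": int((cohort.labels[mask_in] == 1).sum()),
            "n_fp": int((cohort.labels[mask_in] == 0).sum()),
            "n_tn": int((cohort.labels[mask_out] == 0).sum()),
            "n_fn": int((cohort.labels[mask_out] == 1).sum()),
            "n_gray": zc[ZONE_GRAY],
        }
        return OperatingPolicy(
            boundaries=part.boundaries,
            achieved_alpha_plus=part.achieved_alpha_plus(),
            achieved_alpha_minus=part.achieved_alpha_minus(),
            counts=counts,
            gray_fraction=zc[ZONE_GRAY] / cohort.n,
            pathway="A",
        )

    table = ThresholdTable(cohort)
    m = len(table.candidates)
    below = table.pos_below + table.neg_below
    SafetyPolicy.symmetric(alpha_plus if alpha_plus is not None else alpha_minus)

    if alpha_plus is not None:  # Pathway B: fix τ⁺, maximize achieved NPV
        qp = np.where(~np.isnan(table.ppv) & (table.ppv >= alpha_plus))[0]
        j = int(qp[0]) if len(qp) else m - 1
        # feasible τ⁻ candidates: defined NPV, ≤ τ⁺, gray within budget
        gray = below[j] - below
        ok = (
            ~np.isnan(table.npv)
            & (np.arange(m) <= j)
            & (gray <= p_g_max * table.n + 1e-9)
        )
        idx = np.where(ok)[0]
        if len(idx):
            # max NPV, tie-break larger τ⁻ (larger automated zone)
            i = int(idx[np.lexsort((-idx, -table.npv[idx]))[0]])
            feasible = True
        else:
            i = 0  # empty rule-out
            feasible = bool(below[j] <= p_g_max * table.n + 1e-9)
        return _policy_from_pair(cohort, table, i, j, "B", feasible)

    # Pathway C: fix τ⁻ from α⁻, maximize achieved PPV
    qm = np.where(~np.isnan(table.npv) & (table.npv >= alpha_minus))[0]
    i = int(qm[-1]) if len(qm) else 0
    gray = below - below[i]
    ok = (
        ~np.isnan(table.ppv)
        & (np.arange(m) >= i)
        & (gray <= p_g_max * table.n + 1e-9)
    )
    idx = np.where(ok)[0]
    if len(idx):
        # max PPV, tie-break smaller τ⁺ (larger automated zone)
        j = int(idx[np.lexsort((idx, -table.ppv[idx]))[0]])
        feasible = True
    else:
        j = m - 1  # empty rule-in: gray = everything at/above τ⁻
        feasible = bool(table.n - below[i] <= p_g_max * table.n + 1e-9)
    return _policy_from_pair(cohort, table, i, j, "C", feasible)


def _utility_terms(table: ThresholdTable, spec: UtilitySpec):
    """Separable per-candidate utility terms: U(i, j) = f[i] + g[j]."""
    u_tp, u_tn, u_fp, u_fn, u_gray = spec.as_tuple()
    pb, nb = table.pos_below.astype(float), table.neg_below.astype(float)
    f = (u_fn - u_gray) * pb + (u_tn - u_gray) * nb
    g = (
        (u_tp - u_gray) * (table.n_pos - pb)
        + (u_fp - u_gray) * (table.n_neg - nb)
        + u_gray * table.n
    )
    return f, g


def maximize_utility(cohort: ScoredCohort, spec: UtilitySpec) -> OperatingPolicy:
    """Exact argmax of total utility over all candidate pairs τ⁻ ≤ τ⁺."""
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    m = len(table.candidates)
    f, g = _utility_terms(table, spec)

    # stage 1: the maximum value, via prefix maxima of the τ⁻ term
    fmax_prefix = np.maximum.accumulate(f)
    total = fmax_prefix + g
    u_max = total.max()

    # stage 2: tie-break over the maximizing pairs. The tie-break keys are
    # themselves separable integer sums — errors(i,j) = n_fn(i) + n_fp(j),
    # gray(i,j) = below[j] - below[i] — so each side contributes one int64
    # "digit string" and comparing key_i + key_j is lexicographic over
    # (errors, gray, i, j); digit bases are wide enough to prevent carries.
    good_j = np.where(total == u_max)[0]
    n = table.n
    below = (table.pos_below + table.neg_below).astype(np.int64)
    e_i = table.pos_below.astype(np.int64)            # n_fn
    e_j = (table.n_neg - table.neg_below).astype(np.int64)  # n_fp
    base_gray = 2 * n + 2  # gray digit carries an offset of +n
    msq = np.int64(m) * np.int64(m)
    idx = np.arange(m, dtype=np.int64)
    key_i = (e_i * base_gray + (n - below)) * msq + idx * m
    key_j = (e_j * base_gray + below) * msq + idx

    best = None
    for j in good_j:
        # maximizing i's for this j carry the prefix-max f value (exact
        # element comparison; no float reconstruction via subtraction)
        cand_i = np.where(f[: j + 1] == fmax_prefix[j])[0]
        ki = cand_i[np.argmin(key_i[cand_i])]
        key = key_i[ki] + key_j[j]
        if best is None or key < best[0]:
            best = (key, int(ki), int(j))
    i, j = best[1], best[2]

    policy = _policy_from_pair(cohort, table, i, j, "U")
    policy.total_utility = float(u_max)
    c = policy.counts
    rows = [
        ("TP", c["n_tp"], spec.u_tp),
        ("TN", c["n_tn"], spec.u_tn),
        ("FP", c["n_fp"], spec.u_fp),
        ("FN", c["n_fn"], spec.u_fn),
        ("Gray", c["n_gray"], spec.u_gray),
    ]
    policy.utility_table = pd.DataFrame(
        [
            {"outcome": o, "cases": k, "utility": u, "total": k * u}
            for o, k, u in rows
        ]
    )
    return policy


def enumerate_policies(
    cohort: ScoredCohort, spec: UtilitySpec, cap: int = 5000
) -> pd.DataFrame:
    """Full utility landscape: one row per valid candidate pair τ⁻ ≤ τ⁺.

    The table has O(m²) rows; cohorts larger than ``cap`` cases are
    rejected (use :func:`maximize_utility`, which needs no table).
    """
    if cohort.n > cap:
        raise UsageError(
            f"cohort has {cohort.n} cases > cap {cap}; use maximize_utility"
        )
    cohort.require_two_class()
    table = ThresholdTable(cohort)
    m = len(table.candidates)
    f, g = _utility_terms(table, spec)
    ii, jj = np.triu_indices(m)
    pb, nb = table.pos_below, table.neg_below
    n_fn = pb[ii]
    n_tn = nb[ii]
    n_tp = table.n_pos - pb[jj]
    n_fp = table.n_neg - nb[jj]
    n_gray = table.n - n_fn - n_tn - n_tp - n_fp
    return pd.DataFrame(
        {
            "tau_minus": table.candidates[ii],
            "tau_plus": table.candidates[jj],
            "n_tp": n_tp,
            "n_tn": n_tn,
            "n_fp": n_fp,
            "n_fn": n_fn,
            "n_gray": n_gray,
            "u_total": f[ii] + g[jj],
        }
    )
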