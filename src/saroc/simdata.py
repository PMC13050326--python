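"""Synthetic score-cohort generation from Beta-distribution class models.

A scenario draws negative-class scores from Beta(a0, b0) and positive-class
scores from Beta(a1, b1) — the standard simulation design for continuous
risk scores bounded in [0, 1]. The analytic AUC of such a pair,
P(X₁ > X₀) = ∫ F₀(x) f₁(x) dx, is computed by quadrature, and scenario
families with one free parameter can be calibrated to a target AUC by
root-finding:

* ``symmetric-skew``   — neg ~ Beta(1, c), pos ~ Beta(c, 1); free c ≥ 1.
* ``location-shift``   — mirror mean-shift pair at fixed concentration κ = 8:
  neg ~ Beta(κ(½−δ), κ(½+δ)), pos ~ Beta(κ(½+δ), κ(½−δ)); free δ ∈ (0, ½).
* ``overlap-width``    — location-shift with caller-chosen concentration
  ``width``.
* ``one-sided-skew``   — asymmetric pair with one class pinned against an
  endpoint: side ``rule_in`` has pos ~ Beta(c, 1) (mass piled toward 1)
  against a broad low-skew negative Beta(1.5, 3); side ``rule_out`` is the
  mirror image. These produce one strong safe zone at modest AUC.
* ``peak-separation``  — pos ~ Beta(c, 1) narrowly packed against the top of
  the scale with a steep inner tail, over a thin uniform negative background
  (neg ~ Beta(1, 1)); free c. The class crossing mass required by a
  sub-perfect AUC is spread thinly instead of pooled in a shared bulk, so
  strict-safety gray zones stay small and stable.

Four named presets reproduce the canonical scenario contrasts:
``rule_in_skew`` (AUC 0.768) and ``rule_out_skew`` (AUC 0.780) each carve
one strong safe zone at modest AUC; the equal-AUC pair ``wide_overlap``
(overlap-width, κ = 8 — two broad humps overlapping through the midrange)
and ``narrow_separation`` (peak-separation) both calibrate to AUC 0.960 yet
differ sharply in the gray zone left at strict safety levels: the maximal
(α = 100%) gray-zone area depends on how far each class's extreme scores
reach into the other's range, not on the AUC. Default cohort sizes are
5,000 negatives + 5,000 positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .cohort import ScoredCohort
from .errors import CalibrationError, CohortValidationError, ConfigurationError

__all__ = [
    "BetaScenario",
    "PRESETS",
    "sample_scenario",
    "analytic_auc",
    "calibrate_to_auc",
    "preset_scenario",
]

DEFAULT_N = 5000


@dataclass(frozen=True)
class BetaScenario:
    """Beta score model for the two classes plus sampling configuration."""

    a0: float
    b0: float
    a1: float
    b1: float
    n_neg: int = DEFAULT_N
    n_pos: int = DEFAULT_N
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        for nm in ("a0", "b0", "a1", "b1"):
            if not (getattr(self, nm) > 0):
                raise CohortValidationError(f"shape {nm} must be > 0")
        if self.n_neg <= 0 or self.n_pos <= 0:
            raise CohortValidationError("n_neg and n_pos must be positive")

    def to_record(self) -> dict:
        return {
            "a0": self.a0, "b0": self.b0, "a1": self.a1, "b1": self.b1,
            "n_neg": self.n_neg, "n_pos": self.n_pos, "seed": self.seed,
            "name": self.name,
        }


def sample_scenario(scenario: BetaScenario) -> ScoredCohort:
    """Draw a labeled score cohort from the scenario (deterministic in
    ``scenario.seed``); negatives first, then positives."""
    rng = np.random.default_rng(scenario.seed)
    neg = rng.beta(scenario.a0, scenario.b0, scenario.n_neg)
    pos = rng.beta(scenario.a1, scenario.b1, scenario.n_pos)
    scores = np.concatenate((neg, pos))
    labels = np.concatenate(
        (np.zeros(scenario.n_neg, dtype=np.int8), np.ones(scenario.n_pos, dtype=np.int8))
    )
    width = len(str(len(scores)))
    ids = np.array(
        [f"neg_{k:0{width}d}" for k in range(scenario.n_neg)]
        + [f"pos_{k:0{width}d}" for k in range(scenario.n_pos)],
        dtype=object,
    )
    return ScoredCohort(ids, scores, labels)


def analytic_auc(a0: float, b0: float, a1: float, b1: float) -> float:
    """P(X₁ > X₀) for independent Beta score models.

    Computed as ∫ F₀(x) f₁(x) dx after the substitution u = F₁(x), i.e.
    ∫₀¹ F₀(F₁⁻¹(u)) du — the integrand is bounded in [0, 1], so the
    quadrature is robust even for near-degenerate shapes. Absolute
    tolerance 1e-9.
    """
    for v in (a0, b0, a1, b1):
        if not v > 0:
            raise CohortValidationError("shape parameters must be > 0")

    def integrand(u):
        return beta_dist.cdf(beta_dist.ppf(u, a1, b1), a0, b0)

    value, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-9, limit=200)
    if err > 1e-6:
        raise CalibrationError(f"AUC quadrature did not converge (err={err:g})")
    return float(min(max(value, 0.0), 1.0))


def _family_scenario(family: str, param: float, width: float | None, side: str):
    if family == "symmetric-skew":
        return (1.0, param, param, 1.0)
    if family in ("location-shift", "overlap-width"):
        kappa = 8.0 if family == "location-shift" else width
        if kappa is None or kappa <= 0:
            raise ConfigurationError("overlap-width requires a positive width")
        d = param
        return (kappa * (0.5 - d), kappa * (0.5 + d), kappa * (0.5 + d), kappa * (0.5 - d))
    if family == "one-sided-skew":
        if side == "rule_in":
            return (1.5, 3.0, param, 1.0)
        if side == "rule_out":
            return (1.0, param, 3.0, 1.5)
        raise ConfigurationError(f"unknown side {side!r}")
    if family == "peak-separation":
        return (1.0, 1.0, param, 1.0)
    raise ConfigurationError(f"unknown family {family!r}")


_FAMILY_BRACKETS = {
    "symmetric-skew": (1.0 + 1e-9, 500.0),
    "location-shift": (1e-6, 0.5 - 1e-6),
    "overlap-width": (1e-6, 0.5 - 1e-6),
    "one-sided-skew": (1.0 + 1e-9, 500.0),
    "peak-separation": (1.0 + 1e-9, 500.0),
}


def calibrate_to_auc(
    target_auc: float,
    family: str = "location-shift",
    width: float | None = None,
    side: str = "rule_in",
    tol: float = 1e-4,
) -> BetaScenario:
    """Root-find the family's free parameter so the analytic AUC hits
    ``target_auc`` (within ``tol``). Targets must lie in (0.5, 1)."""
    if not (0.5 < target_auc < 1.0):
        raise CalibrationError(f"target AUC must lie in (0.5, 1), got {target_auc}")
    lo, hi = _FAMILY_BRACKETS.get(family, (None, None))
    if lo is None:
        raise ConfigurationError(f"unknown family {family!r}")

    def objective(param):
        return analytic_auc(*_family_scenario(family, param, width, side)) - target_auc

    f_lo, f_hi = objective(lo), objective(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"target AUC {target_auc} unattainable in family {family!r} "
            f"(range {f_lo + target_auc:.4f}–{f_hi + target_auc:.4f})"
        )
    param = brentq(objective, lo, hi, xtol=1e-10, rtol=1e-12)
    a0, b0, a1, b1 = _family_scenario(family, param, width, side)
    achieved = analytic_auc(a0, b0, a1, b1)
    if abs(achieved - target_auc) > tol:
        raise CalibrationError(
            f"calibration residual {abs(achieved - target_auc):g} exceeds {tol}"
        )
    return BetaScenario(a0, b0, a1, b1, name=f"{family}(auc={target_auc:g})")


#: Named scenario presets: (family, target AUC, extra kwargs).
PRESETS = {
    "rule_in_skew": ("one-sided-skew", 0.768, {"side": "rule_in"}),
    "rule_out_skew": ("one-sided-skew", 0.780, {"side": "rule_out"}),
    "wide_overlap": ("overlap-width", 0.960, {"width": 8.0}),
    "narrow_separation": ("peak-separation", 0.960, {}),
}


def preset_scenario(
    name: str, n_neg: int = DEFAULT_N, n_pos: int = DEFAULT_N, seed: int = 0
) -> BetaScenario:
    """Calibrated scenario for one of the named presets."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; one of {sorted(PRESETS)}")
    family, target, kwargs = PRESETS[name]
    scenario = calibrate_to_auc(target, family=family, **kwargs)
    return replace(scenario, n_neg=n_neg, n_pos=n_pos, seed=seed, name=name)
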