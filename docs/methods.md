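# Methods

## Model and definitions

The unit of analysis is a scored cohort: cases `i` with a continuous risk
score `s_i ∈ [0, 1]` (closed interval; exact 0 and 1 are legal), a binary
reference label `y_i`, and optionally the human reader's binary call. A
positive call at threshold τ is `s_i ≥ τ`; a negative call is `s_i < τ`.
PPV(τ) and NPV(τ) are the precisions of the two call sets and are
*undefined* (not 0, not 1) when the respective call set is empty — an empty
denominator is a vacuous reliability claim and never opens a safe zone.

A safety policy is a pair of reliability targets `(α⁺, α⁻) ∈ (0, 1]²`: the
minimum acceptable PPV for autonomous rule-in and minimum acceptable NPV for
autonomous rule-out. The raw boundaries are

```
τ⁺ = inf { τ : PPV(τ) defined and ≥ α⁺ }
τ⁻ = sup { τ : NPV(τ) defined and ≥ α⁻ }
```

searched over the finite candidate grid: the ascending unique scores plus a
below-min sentinel (call everything positive; an empty rule-out zone) and an
above-max sentinel (call nothing positive; an empty rule-in zone). Because
the grid is finite, the inf/sup are attained, so PPV(τ⁺) ≥ α⁺ and
NPV(τ⁻) ≥ α⁻ hold *at the boundary* whenever the corresponding zone is
nonempty — an in-sample guarantee by construction, not an out-of-sample
coverage statement (see Limitations).

## Overlap resolution

Under lenient targets the raw boundaries can cross (τ⁻ > τ⁺): both
reliability claims hold over overlapping score ranges and the three-zone
partition is ill-defined. Three candidate resolutions were evaluated on
thousands of random cohorts before one was adopted:

1. *Clip τ⁻ := τ⁺.* Keeps the gray zone empty, but the clipped rule-out
   zone's NPV can drop below α⁻ (non-monotone NPV dips), silently breaking
   the reliability contract.
2. *Re-search τ⁻ among qualifying candidates ≤ τ⁺.* Restores the
   reliability contract but can make the gray fraction non-monotone in the
   symmetric safety level (the rising τ⁺ ceiling can admit a new, higher
   qualifying τ⁻ at a stricter α).
3. *Minimal-gray qualifying pair* (adopted): choose, among all pairs
   (τ⁻ at a candidate meeting α⁻ or the empty sentinel, τ⁺ at a candidate
   meeting α⁺ or the empty sentinel, τ⁻ ≤ τ⁺), the pair leaving the fewest
   cases in the gray zone; ties resolve toward the smaller τ⁺ (larger
   rule-in zone — escalation is the fail-safe direction) and then the
   larger τ⁻.

Rule 3 has three provable properties: it reduces *exactly* to the raw
inf/sup boundaries whenever they do not cross (any qualifying pair's gray
interval contains the raw pair's); every nonempty zone meets its target by
construction; and the gray fraction is non-decreasing in the symmetric
safety level, because the qualifying pair set only shrinks as α grows, so
the minimal gray count cannot decrease. Crossed raw boundaries are surfaced
via the `clipped` flag and a logged warning.

## Workload metrics

The gray-zone fraction is the share of cases assigned to the gray zone by
the (overlap-resolved) partition. The gray-zone area

```
Γ_Area = FPR(τ⁻) × (1 − TPR(τ⁺))
```

is always computed from the **raw** boundaries — it measures the ROC-space
cost of the two reliability searches independently of how a partition
resolves their overlap. With raw boundaries Γ_Area is provably
non-decreasing in the symmetric safety level (τ⁻ non-increasing ⇒ FPR(τ⁻)
non-decreasing; τ⁺ non-decreasing ⇒ miss rate non-decreasing). Empty-zone
sentinels degrade gracefully: an empty rule-out zone contributes FPR = 1,
an empty rule-in zone contributes TPR = 0, and Γ_Area = 1 when nothing is
automatable. A side effect of the raw-boundary convention: when zones
overlap (empty gray), Γ_Area can still be positive; it is then an index of
the unresolved ROC-space indecision, not of deferred cases.

The safety profile evaluates both metrics over an α grid, default 0.50 to
1.00 in steps of 0.005 (101 points) in the symmetric convention α⁺ = α⁻;
asymmetric one-sided profiles fix the other target.

## Operating policies

*Constraint pathways.* Exactly two of {α⁺, α⁻, p_g_max} are fixed.
Pathway A (both reliabilities) is the plain partition. Pathways B/C fix one
reliability (which pins its boundary) and maximize the *achieved* opposite
reliability — the PPV/NPV attained at the chosen boundary — subject to the
gray fraction not exceeding the budget and to contiguity (τ⁻ ≤ τ⁺). The
attained value is itself the best achievable target by discreteness, so no
α-grid search (and no grid-resolution artifact) is involved. Ties go to the
larger automated zone. Because the boundary pair may always collapse
(τ⁻ = τ⁺, empty gray), a workload budget alone can never be infeasible;
what *can* happen is an unattainable reliability target, which surfaces as
an empty zone (e.g. a 100% NPV demand on a cohort whose lowest scores
include a positive eliminates autonomous rule-out entirely).

*Utility maximization.* Each case outcome carries a finite per-case utility
(U_TP, U_TN, U_FP, U_FN, U_Gray); the total utility of a boundary pair is
the count-weighted sum, and the optimizer returns the exact argmax over all
candidate pairs τ⁻ ≤ τ⁺. Implementation: the total separates into a τ⁻ term
and a τ⁺ term over prefix counts, so the maximum is found with prefix maxima
in O(m log m) rather than O(m²); the tie-break (fewest errors n_FP + n_FN,
then fewest deferrals, then lexicographically smallest (τ⁻, τ⁺)) is also
separable and resolved with carry-free integer keys. `enumerate_policies`
materializes the full O(m²) landscape for inspection and serves as the
oracle the optimizer is tested against; it is capped (default 5,000 cases)
because the table, unlike the optimizer, is quadratic in memory.

## Resampling

*Bootstrap.* Percentile intervals (2.5th/97.5th) from B = 2000 (default)
with-replacement resamples; the statistic — AUC, Γ_Area, gray fraction, or
the rule-out true-negative count — is recomputed per replicate, *including
re-deriving the zone boundaries*, which is what makes interval widths honest
about threshold instability. Freezing the boundaries at their full-cohort
values is available as a flag (default off) for isolating sampling noise at
a fixed policy. The RNG recipe is documented and deliberately simple —
`numpy.random.default_rng(seed)`, replicate indices `rng.integers(0, n, n)`,
single-class replicates discarded and redrawn from the same stream with the
redraw count reported — so an independent reimplementation reproduces the
bounds bit-for-bit. If more than half of the replicates leave the statistic
undefined, the interval is refused rather than silently narrowed.

*Prevalence shift.* PPV and NPV are prevalence-dependent, so zones move
under case-mix shift. The sweep holds the complete negative set fixed
(maximizing the stability of the reference distribution) and resamples
positives with replacement to `round_half_even(n_neg · p / (1 − p))` per
target prevalence p, recomputing the partition per replicate. Realized
prevalence is within 1/n of the target by the rounding rule.

*Two-model comparison.* For two models scored on identical cases, the
rule-out capacity difference (true negatives inside each model's rule-out
zone at α⁻, model B − model A) is bootstrapped with a *paired* case-level
resample: one index draw applies to both score columns, preserving the
per-case correlation between models. The statistic is antisymmetric under
swapping the models and exactly zero whenever the two score columns are
rank-equivalent. Zone concordance (the 3×3 cross-model contingency of zone
assignments) complements the scalar difference.

*Reader stratification.* Cases are grouped by the AI's zones — each
requested (zone, α) computed independently, so nested levels appear as
separate rows — and the human reader's outcome mix (TP/TN/FP/FN against the
same reference standard) and accuracy are tabulated per zone. Cases without
a reader call are excluded from this analysis only, with a logged count.

## Synthetic cohorts

The simulator draws class-conditional scores from a pair of Beta
distributions — negatives from Beta(a0, b0), positives from Beta(a1, b1) —
the natural bounded-support model for probability-like classifier outputs.
Default sizes are 5,000 + 5,000. The analytic AUC, P(X₁ > X₀), is computed
by quadrature of ∫₀¹ F₀(F₁⁻¹(u)) du (the probability-scale substitution
keeps the integrand bounded even for near-degenerate shapes; absolute
tolerance 1e-9, verified against large Monte Carlo in the tests), and
scenario families with one free parameter are calibrated to a target AUC by
Brent root-finding to within 1e-4.

Presets:

* `rule_in_skew` (AUC 0.768) — positives piled toward 1 over a broad
  low-skew negative background: a modest-AUC model with a strong rule-in
  zone.
* `rule_out_skew` (AUC 0.780) — the mirror image: strong rule-out.
* `wide_overlap` (AUC 0.960) — mirror mean-shift pair at concentration
  κ = 8: two broad humps overlapping through the midrange.
* `narrow_separation` (AUC 0.960) — positives narrowly packed at the top
  (Beta(24, 1); the AUC target is met exactly since P(X₁ > X₀) = c/(c+1)
  for a uniform negative background), with the class-crossing mass spread
  thinly rather than pooled in a shared bulk.

The last two exist to demonstrate that equal AUC does not mean equal
automatable workload. At the maximal safety level the gray-zone area is
governed by how far each class's *extreme* scores reach into the other's
range — an extreme-order-statistic property invisible to AUC. Within pure
mirror Beta pairs this contrast is not robust: at fixed AUC 0.96 the
maximal-safety Γ_Area of the mean-shift family stays in ≈0.5–0.77 for every
concentration tested (κ from 0.8 to 300), with seed-to-seed spread large
enough to flip any ordering, because the 1/n-quantiles of two overlapping
humps always dive deep into the opposite bulk. The adopted preset pair
separates by ≈0.35 in Γ_Area with per-seed spread ≈0.05, and the ordering
held on every seed tested.

What the simulator does *not* emulate: miscalibrated or discretized vendor
scores, per-site case-mix heterogeneity, correlated reader behavior, or
multimodal score distributions. Passing tests on these cohorts therefore
demonstrate correctness of the zone/metric/policy machinery, not clinical
performance of any real model.

## Numerical choices and degenerate inputs

* Reliability comparisons use plain `≥` on exact count ratios; no epsilon.
* Youden's threshold scans the unique scores plus the above-max sentinel;
  ties favor the higher TPR, then the lower threshold (sensitivity-first).
  An all-tied cohort returns its single score with J = 0.
* Single-class cohorts are valid containers (summaries work) but every
  two-class computation refuses them explicitly.
* Bootstrap replicates that lose a class are redrawn, keeping B effective
  replicates; degenerate separated cohorts yield zero-width intervals.
* Scores are never binned; candidate grids come from the exact unique
  values, so ties are first-class citizens throughout.
* All randomness flows through a single `default_rng(seed)` per operation;
  seeds are echoed in every result object.

## Limitations

* Zone reliabilities are in-sample (resubstitution) guarantees; at strict
  targets the boundaries ride on sparse score tails and can be unstable —
  the bootstrap quantifies but does not remove this. Split-sample or
  conformal-style calibration is out of scope.
* Γ_Area compares models on the same cohort; it is not transportable across
  case mixes (PPV/NPV are prevalence-dependent — that is the point of the
  prevalence sweep).
* The paired-comparison bootstrap is one defensible scheme among several;
  alternatives (e.g. stratified resampling) would give slightly different
  interval widths.
* Utilities are per-case constants; covariate-dependent utilities and
  sequential/RL policy optimization are out of scope.
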