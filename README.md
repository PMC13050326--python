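# saroc — safety-aware ROC analysis for clinical classifier scores

A binary classifier with an excellent AUC can still be unsafe to act on: AUC
says nothing about *where* on the score scale the model's predictions are
reliable enough for autonomous use. `saroc` answers the operational question
— *under which conditions can a clinician trust the model's call?* — by
partitioning a model's score range into three zones under explicit,
clinician-set reliability targets:

* **Rule-in safe zone** `{s ≥ τ⁺}` — positive calls here have in-sample
  PPV ≥ α⁺; eligible for autonomous escalation.
* **Rule-out safe zone** `{s < τ⁻}` — negative calls here have in-sample
  NPV ≥ α⁻; eligible for autonomous de-prioritization.
* **Gray zone** — everything in between; mandatory human review.

The boundaries come from an exhaustive scan over the empirical thresholds:

```
τ⁺ = inf { τ : PPV(τ) ≥ α⁺ },    τ⁻ = sup { τ : NPV(τ) ≥ α⁻ },
```

with positive calls defined by `score ≥ τ`. Thresholds whose PPV/NPV has an
empty denominator never qualify. The deferred workload is quantified two
ways: the **gray-zone fraction** (share of the cohort needing review) and
the **gray-zone area**

```
Γ_Area = FPR(τ⁻) × (1 − TPR(τ⁺)),
```

the rectangle in ROC space spanned by the false-positive rate at the
rule-out boundary and the miss rate at the rule-in boundary — the geometric
cost of indecision (1.0 when nothing is automatable). Operating policies can
also be derived from clinical goals: fix any two of {α⁺, α⁻, gray-budget
p_g} and the third is optimized, or assign per-case utilities
(U_TP, U_TN, U_FP, U_FN, U_Gray) and `saroc` finds the exact utility-maximal
threshold pair

```
U_Total = n_TP·U_TP + n_TN·U_TN + n_FP·U_FP + n_FN·U_FN + n_Gray·U_Gray.
```

Stability is characterized with percentile bootstrap CIs (boundaries
re-derived per resample) and prevalence-shift resampling (negatives held
fixed, positives resampled to a target prevalence). A Beta-distribution
cohort simulator with calibratable AUC makes every analysis runnable with no
external data.

**Audience:** clinical-AI evaluation teams, AI governance committees, and
method developers who consume per-case model scores (never images) from CSV
or TSV files.

## Worked example

An 8-case cohort — positives scoring {0.9, 0.8, 0.7, 0.4}, negatives
{0.6, 0.3, 0.2, 0.1} — at maximal symmetric safety (α⁺ = α⁻ = 100%):

```python
import saroc

cohort = saroc.ScoredCohort(
    [f"case{i}" for i in range(8)],
    [0.9, 0.8, 0.7, 0.4, 0.6, 0.3, 0.2, 0.1],
    [1, 1, 1, 1, 0, 0, 0, 0],
)
part = saroc.make_partition(cohort, saroc.SafetyPolicy(1.0, 1.0))
print("AUC      ", saroc.auc(cohort))
print("tau_minus", part.boundaries.tau_minus, " tau_plus", part.boundaries.tau_plus)
print("gray     ", saroc.gray_fraction(part), " gamma", saroc.gray_area(cohort, part.boundaries))
print("theta    ", saroc.youden_theta(cohort))
```

prints

```
AUC       0.9375
tau_minus 0.4  tau_plus 0.7
gray      0.25  gamma 0.0625
theta     0.4
```

Read: the model ranks well (AUC 0.94). Scores ≥ 0.7 can be escalated
autonomously (every such call is a true positive in-sample) and scores
< 0.4 can be ruled out autonomously; the two cases scoring 0.4 and 0.6 (25%
of the cohort) are not reliable in either direction and must be reviewed by
a human. Γ_Area = 0.25 × 0.25 = 0.0625 locates that burden in ROC space.
The Youden threshold 0.4 shows that the *statistically* optimal single
cutoff sits inside the gray zone — a single-threshold deployment would act
autonomously exactly where the model is least trustworthy.

The same analyses run from the shell:

```bash
saroc simulate --preset wide_overlap --seed 1 -o sim/       # synthetic cohort
saroc zones sim/cohort.csv --alpha-plus 0.95 --alpha-minus 0.99 -o out/
saroc profile sim/cohort.csv --plot -o out/                 # safety profile
saroc policy sim/cohort.csv --config policy.yaml -o out/    # constraints or utility
saroc bootstrap sim/cohort.csv --statistic gamma_area --alpha 1.0 -o out/
saroc compare sim_a/cohort.csv sim_b/cohort.csv --alpha 1.0 -o out/
```

Every command writes a `manifest.json` with the resolved parameters, and
every figure comes with a JSON sidecar holding the exact plotted numbers.

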