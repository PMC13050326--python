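"""Constraint pathways and utility maximization."""

import numpy as np
import pytest

import saroc
from saroc import SafetyPolicy, ScoredCohort, UtilitySpec

import oracles
from conftest import random_cohort


def test_pathway_a_toy(toy_cohort):
    pol = saroc.solve_constraints(toy_cohort, alpha_plus=1.0, alpha_minus=1.0)
    assert pol.pathway == "A"
    assert pol.gray_fraction == pytest.approx(0.25)
    assert pol.counts == {"n_tp": 3, "n_fp": 0, "n_tn": 3, "n_fn": 0, "n_gray": 2}
    assert pol.achieved_alpha_plus == 1.0 and pol.achieved_alpha_minus == 1.0


def test_pathway_a_matches_partition():
    rng = np.random.default_rng(12)
    for _ in range(30):
        c = random_cohort(rng)
        a = float(rng.uniform(0.5, 1.0))
        pol = saroc.solve_constraints(c, alpha_plus=a, alpha_minus=a)
        part = saroc.make_partition(c, SafetyPolicy(a, a))
        assert pol.boundaries.tau_minus == part.boundaries.tau_minus
        assert pol.boundaries.tau_plus == part.boundaries.tau_plus
        assert pol.counts["n_gray"] == int((part.assignment == "GRAY").sum())


def test_pathway_c_toy(toy_cohort):
    pol = saroc.solve_constraints(toy_cohort, alpha_minus=1.0, p_g_max=0.25)
    assert pol.pathway == "C"
    assert pol.boundaries.tau_minus == 0.4
    assert pol.boundaries.tau_plus == 0.7
    assert pol.achieved_alpha_plus == 1.0
    assert pol.feasible


def test_pathway_b_toy(toy_cohort):
    # best achievable rule-out reliability under an unconstraining budget is
    # NPV = 1.0, attained with the largest zone at tau_minus = 0.4
    pol = saroc.solve_constraints(toy_cohort, alpha_plus=1.0, p_g_max=1.0)
    assert pol.pathway == "B"
    assert pol.boundaries.tau_plus == 0.7
    assert pol.boundaries.tau_minus == 0.4
    assert pol.achieved_alpha_minus == 1.0


def test_pathway_b_budget_binds(toy_cohort):
    # gray budget 0: tau_minus must rise to tau_plus; NPV(0.7) = 4/5
    pol = saroc.solve_constraints(toy_cohort, alpha_plus=1.0, p_g_max=0.0)
    assert pol.boundaries.tau_minus == 0.7
    assert pol.gray_fraction == 0.0
    assert pol.achieved_alpha_minus == pytest.approx(0.8)


def test_pathways_never_exceed_budget():
    rng = np.random.default_rng(13)
    for _ in range(60):
        c = random_cohort(rng)
        budget = float(rng.uniform(0, 0.6))
        a = float(rng.uniform(0.6, 1.0))
        for kwargs in ({"alpha_plus": a}, {"alpha_minus": a}):
            pol = saroc.solve_constraints(c, p_g_max=budget, **kwargs)
            if pol.feasible:
                assert pol.gray_fraction <= budget + 1e-9
                # achieved reliability meets the fixed target's zone guarantee
                if "alpha_plus" in kwargs and not np.isnan(pol.achieved_alpha_plus):
                    assert pol.achieved_alpha_plus >= a - 1e-12
                if "alpha_minus" in kwargs and not np.isnan(pol.achieved_alpha_minus):
                    assert pol.achieved_alpha_minus >= a - 1e-12


def test_unattainable_target_yields_empty_zone_not_exception():
    # all scores tied: a perfect rule-in PPV is unattainable, so the rule-in
    # zone comes back empty; the budget is met by collapsing the gray zone
    # (everything is ruled out at the best defined NPV)
    c = ScoredCohort(["a", "b", "c", "d"], [0.5] * 4, [1, 0, 1, 0])
    pol = saroc.solve_constraints(c, alpha_plus=1.0, p_g_max=0.1)
    assert pol.boundaries.rule_in_empty
    assert pol.counts["n_tp"] == 0 and pol.counts["n_fp"] == 0
    assert pol.gray_fraction <= 0.1
    assert pol.achieved_alpha_minus == 0.5


def test_constraint_arity():
    c = ScoredCohort(["a", "b"], [0.2, 0.9], [0, 1])
    with pytest.raises(saroc.UsageError):
        saroc.solve_constraints(c, alpha_plus=0.9)
    with pytest.raises(saroc.UsageError):
        saroc.solve_constraints(c, alpha_plus=0.9, alpha_minus=0.9, p_g_max=0.5)


def test_maximize_utility_toy(toy_cohort):
    pol = saroc.maximize_utility(toy_cohort, UtilitySpec(1, 1, 0, 0, 0))
    assert pol.total_utility == 7.0
    # tie among collapsed single-threshold policies resolved to (0.4, 0.4)
    assert pol.boundaries.tau_minus == 0.4 and pol.boundaries.tau_plus == 0.4
    table = pol.utility_table.set_index("outcome")["total"]
    assert table.sum() == 7.0


def test_maximize_utility_gray_dominates(toy_cohort):
    pol = saroc.maximize_utility(toy_cohort, UtilitySpec(0, 0, 0, 0, 1))
    assert pol.counts["n_gray"] == 8
    assert pol.total_utility == 8.0


def test_maximize_utility_separated_no_errors():
    c = ScoredCohort(["a", "b", "c", "d"], [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    pol = saroc.maximize_utility(c, UtilitySpec(1, 1, -10, -10, 0))
    assert pol.total_utility == 4.0
    assert pol.counts["n_fp"] == 0 and pol.counts["n_fn"] == 0


def test_enumerate_policies_toy(toy_cohort):
    spec = UtilitySpec(1, 1, 0, 0, 0)
    table = saroc.enumerate_policies(toy_cohort, spec)
    assert len(table) == 55  # 10 candidates -> 10*11/2 ordered pairs
    assert table["u_total"].max() == saroc.maximize_utility(toy_cohort, spec).total_utility


def test_enumerate_all_zero_spec(toy_cohort):
    table = saroc.enumerate_policies(toy_cohort, UtilitySpec(0, 0, 0, 0, 0))
    assert (table["u_total"] == 0).all()


def test_enumerate_cap():
    rng = np.random.default_rng(1)
    c = random_cohort(rng, n_min=30, n_max=30)
    with pytest.raises(saroc.UsageError):
        saroc.enumerate_policies(c, UtilitySpec(1, 1, 0, 0, 0), cap=10)


def test_maximize_matches_bruteforce_oracle():
    """Value and tie-broken thresholds equal exhaustive enumeration."""
    rng = np.random.default_rng(99)
    for _ in range(60):
        c = random_cohort(rng, n_max=25)
        u = tuple(np.round(rng.uniform(-5, 5, 5), 2))
        pol = saroc.maximize_utility(c, UtilitySpec(*u))
        u_best, tm, tp = oracles.utility_argmax(list(c.scores), list(c.labels), *u)
        assert pol.total_utility == pytest.approx(u_best, abs=1e-9)
        assert (pol.boundaries.tau_minus, pol.boundaries.tau_plus) == (tm, tp)


def test_maximize_matches_enumerate_random():
    rng = np.random.default_rng(123)
    for _ in range(100):
        c = random_cohort(rng, n_max=60)
        spec = UtilitySpec(*np.round(rng.uniform(-3, 3, 5), 3))
        pol = saroc.maximize_utility(c, spec)
        table = saroc.enumerate_policies(c, spec)
        assert pol.total_utility == pytest.approx(table["u_total"].max(), abs=1e-9)


def test_u_gray_monotone_comparative_statics():
    """Raising the deferral utility never shrinks the optimal gray zone."""
    rng = np.random.default_rng(55)
    for _ in range(40):
        c = random_cohort(rng, n_max=40)
        base = np.round(rng.uniform(-2, 2, 4), 2)
        grays = []
        for ug in (-1.0, 0.0, 0.5, 1.0, 2.5):
            pol = saroc.maximize_utility(c, UtilitySpec(*base, ug))
            grays.append(pol.counts["n_gray"])
        assert all(a <= b for a, b in zip(grays, grays[1:]))


def test_utility_argmax_invariant_under_monotone_transform():
    rng = np.random.default_rng(77)
    for _ in range(30):
        c = random_cohort(rng, n_max=40)
        spec = UtilitySpec(*np.round(rng.uniform(-3, 3, 5), 2))
        pol1 = saroc.maximize_utility(c, spec)
        c2 = ScoredCohort(c.case_ids, c.scores ** 2, c.labels)
        pol2 = saroc.maximize_utility(c2, spec)
        assert pol1.counts == pol2.counts
        assert pol1.total_utility == pytest.approx(pol2.total_utility)


def test_utility_spec_validation():
    with pytest.raises(saroc.UsageError):
        UtilitySpec(1, 1, float("nan"), 0, 0)
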