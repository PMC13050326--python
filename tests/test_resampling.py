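"""Bootstrap intervals, prevalence sweeps, paired comparison, stratification."""

import math

import numpy as np
import pytest

import saroc
from saroc import SafetyPolicy, ScoredCohort

import oracles
from conftest import make_toy_cohort, random_cohort


def test_bootstrap_determinism(toy_cohort):
    a = saroc.bootstrap_interval(toy_cohort, "auc", B=100, seed=7)
    b = saroc.bootstrap_interval(toy_cohort, "auc", B=100, seed=7)
    assert (a.lower, a.upper, a.point) == (b.lower, b.upper, b.point)
    c = saroc.bootstrap_interval(toy_cohort, "auc", B=100, seed=8)
    assert (a.lower, a.upper) != (c.lower, c.upper)


def test_bootstrap_degenerate_separated_cohort():
    c = ScoredCohort([f"c{i}" for i in range(40)],
                     [1.0] * 20 + [0.0] * 20, [1] * 20 + [0] * 20)
    est = saroc.bootstrap_interval(c, "auc", B=50, seed=1)
    assert est.point == 1.0 and est.lower == 1.0 and est.upper == 1.0


def test_bootstrap_matches_independent_reimplementation(toy_cohort):
    """Same seed + documented RNG recipe => identical percentile bounds."""
    est = saroc.bootstrap_interval(toy_cohort, "auc", B=200, seed=31)
    lo, hi = oracles.bootstrap_auc_interval(
        list(toy_cohort.scores), list(toy_cohort.labels), B=200, seed=31)
    assert est.lower == pytest.approx(lo, abs=1e-12)
    assert est.upper == pytest.approx(hi, abs=1e-12)


def test_bootstrap_zone_statistics_run():
    rng = np.random.default_rng(0)
    c = random_cohort(rng, n_min=60, n_max=60)
    for stat in ("gamma_area", "gray_fraction", "rule_out_tn_count"):
        est = saroc.bootstrap_interval(c, stat, B=60, seed=3, alpha=0.9)
        assert est.lower <= est.upper
        assert est.B == 60
    with pytest.raises(saroc.UsageError):
        saroc.bootstrap_interval(c, "gamma_area", B=10, seed=0)  # alpha missing


def test_bootstrap_freeze_boundaries_differs():
    rng = np.random.default_rng(4)
    c = random_cohort(rng, n_min=80, n_max=80)
    free = saroc.bootstrap_interval(c, "gamma_area", B=80, seed=5, alpha=0.95)
    frozen = saroc.bootstrap_interval(c, "gamma_area", B=80, seed=5, alpha=0.95,
                                      freeze_boundaries=True)
    assert free.point == frozen.point  # same point estimate on the full cohort


def test_prevalence_target_rounding():
    # 600 negatives at 1% -> round(600 * 0.01/0.99) = 6 positives
    assert saroc.resampling.target_positive_count(600, 0.01) == 6
    assert saroc.resampling.target_positive_count(600, 0.40) == 400


def test_prevalence_sweep_conserves_negatives():
    rng = np.random.default_rng(21)
    scores = np.concatenate([rng.beta(2, 5, 60), rng.beta(5, 2, 40)])
    c = ScoredCohort([f"c{i}" for i in range(100)], scores,
                     [0] * 60 + [1] * 40)
    neg_scores = np.sort(c.scores[c.labels == 0])
    scenarios = saroc.prevalence_sweep(c, [0.10, 0.40], alpha_minus=0.95, B=20, seed=2)
    for sc in scenarios:
        assert sc.n_negatives_fixed == 60
        k = saroc.resampling.target_positive_count(60, sc.target_prevalence)
        assert sc.n_positives_target == k
        realized = sc.replicates["realized_prevalence"]
        n_total = 60 + k
        assert (abs(realized - sc.target_prevalence) <= 1.0 / n_total + 1e-12).all()


def test_prevalence_identity_target():
    c = ScoredCohort([f"c{i}" for i in range(10)],
                     np.linspace(0.05, 0.95, 10), [0] * 5 + [1] * 5)
    assert saroc.resampling.target_positive_count(5, 0.5) == 5


def test_prevalence_zero_positives_error():
    c = ScoredCohort([f"c{i}" for i in range(10)],
                     np.linspace(0.05, 0.95, 10), [0] * 5 + [1] * 5)
    with pytest.raises(saroc.UsageError):
        saroc.prevalence_sweep(c, [0.01], alpha_minus=1.0, B=5, seed=0)


def _paired_cohorts():
    """20 cases where model B confidently rules out 3 more true negatives
    than model A at maximal safety (checked by the boundary oracle)."""
    labels = [0] * 12 + [1] * 8
    ids = [f"c{i}" for i in range(20)]
    # model A: 5 negatives below every positive
    scores_a = ([0.05, 0.06, 0.07, 0.08, 0.09] + [0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65]
                + [0.3, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.99])
    # model B: 8 negatives below every positive
    scores_b = ([0.05, 0.06, 0.07, 0.08, 0.09, 0.10, 0.11, 0.12] + [0.4, 0.5, 0.6, 0.65]
                + [0.35, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.99])
    a = ScoredCohort(ids, scores_a, labels)
    b = ScoredCohort(ids, scores_b, labels)
    # oracle sanity on the construction
    ta = oracles.rule_out_boundary(scores_a, labels, 1.0)
    tb = oracles.rule_out_boundary(scores_b, labels, 1.0)
    na = sum(1 for s, y in zip(scores_a, labels) if y == 0 and s < ta)
    nb = sum(1 for s, y in zip(scores_b, labels) if y == 0 and s < tb)
    assert nb - na == 3
    return a, b


def test_paired_difference_point_and_ci():
    a, b = _paired_cohorts()
    est = saroc.paired_model_difference(a, b, alpha_minus=1.0, B=200, seed=11)
    assert est.point == 3.0
    assert est.lower <= est.point <= est.upper


def test_paired_difference_self_comparison(toy_cohort):
    est = saroc.paired_model_difference(toy_cohort, toy_cohort, 1.0, B=50, seed=0)
    assert (est.point, est.lower, est.upper) == (0.0, 0.0, 0.0)


def test_paired_difference_rank_invariance(toy_cohort):
    b = ScoredCohort(toy_cohort.case_ids, toy_cohort.scores ** 2, toy_cohort.labels)
    est = saroc.paired_model_difference(toy_cohort, b, 1.0, B=50, seed=0)
    assert (est.point, est.lower, est.upper) == (0.0, 0.0, 0.0)


def test_paired_difference_antisymmetric():
    a, b = _paired_cohorts()
    ab = saroc.paired_model_difference(a, b, 1.0, B=100, seed=9)
    ba = saroc.paired_model_difference(b, a, 1.0, B=100, seed=9)
    assert ab.point == -ba.point


def test_paired_difference_case_mismatch(toy_cohort):
    other = ScoredCohort(["x0"] + [f"case{i}" for i in range(1, 8)],
                         toy_cohort.scores, toy_cohort.labels)
    with pytest.raises(saroc.CohortValidationError):
        saroc.paired_model_difference(toy_cohort, other, 1.0, B=10, seed=0)


def test_zone_concordance_identity(toy_cohort):
    part = saroc.make_partition(toy_cohort, SafetyPolicy(1.0, 1.0))
    conc = saroc.zone_concordance(part, part)
    assert np.trace(conc.to_numpy()) == 8
    assert conc.to_numpy().sum() == 8


def test_zone_concordance_reversed_scores(toy_cohort):
    rev = ScoredCohort(toy_cohort.case_ids, 1.0 - toy_cohort.scores, toy_cohort.labels)
    pa = saroc.make_partition(toy_cohort, SafetyPolicy(1.0, 1.0))
    pb = saroc.make_partition(rev, SafetyPolicy(1.0, 1.0))
    conc = saroc.zone_concordance(pa, pb)
    # margins equal each partition's zone sizes
    za = {z: int((pa.assignment == z).sum()) for z in ("RULE_OUT", "GRAY", "RULE_IN")}
    zb = {z: int((pb.assignment == z).sum()) for z in ("RULE_OUT", "GRAY", "RULE_IN")}
    assert conc.sum(axis=1).to_dict() == za
    assert conc.sum(axis=0).to_dict() == zb
    # direct counting oracle
    for x in conc.index:
        for y in conc.columns:
            direct = int(np.count_nonzero((pa.assignment == x) & (pb.assignment == y)))
            assert conc.loc[x, y] == direct


def test_stratify_perfect_reader():
    c = make_toy_cohort(reader_calls=[1, 1, 1, 1, 0, 0, 0, 0])
    table = saroc.stratify_reader_outcomes(c, [("rule_in", 1.0), ("rule_out", 1.0),
                                               ("gray", 1.0)])
    nonempty = table[table["size"] > 0]
    assert (nonempty["accuracy"] == 1.0).all()


def test_stratify_overcalling_reader():
    # reader calls everything positive: rule-out zone (all true negatives at
    # maximal safety) scores accuracy 0
    c = make_toy_cohort(reader_calls=[1] * 8)
    table = saroc.stratify_reader_outcomes(c, [("rule_out", 1.0)])
    row = table.iloc[0]
    assert row["size"] == 3 and row["accuracy"] == 0.0 and row["n_fp"] == 3


def test_stratify_counts_match_direct(toy_cohort):
    calls = [1, 0, 1, 1, 1, 0, 1, 0]
    c = make_toy_cohort(reader_calls=calls)
    table = saroc.stratify_reader_outcomes(c)
    # count conservation per alpha level: rule_in + gray + rule_out at 0.90
    sub = table[table["alpha"] == 0.90]
    assert sub["size"].sum() == 8
    # spot-check one zone against direct counting
    tau = saroc.rule_out_boundary(c, 1.0)
    mask = c.scores < tau
    row = table[(table["zone"] == "rule_out") & (table["alpha"] == 1.0)].iloc[0]
    assert row["size"] == int(mask.sum())
    tn = sum(1 for k in np.where(mask)[0] if calls[k] == 0 and c.labels[k] == 0)
    assert row["n_tn"] == tn


def test_stratify_empty_zone_row():
    c = ScoredCohort(["a", "b", "c", "d"], [0.5] * 4, [1, 0, 1, 0],
                     reader_calls=[1, 0, 1, 0])
    table = saroc.stratify_reader_outcomes(c, [("rule_in", 1.0)])
    assert table.iloc[0]["size"] == 0
    assert math.isnan(table.iloc[0]["accuracy"])


def test_stratify_requires_reader(toy_cohort):
    with pytest.raises(saroc.CohortValidationError):
        saroc.stratify_reader_outcomes(toy_cohort)
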