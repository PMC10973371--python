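"""Kaplan-Meier, log-rank, Pearson correlation and time-dependent AUC."""

import itertools

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

import _oracles as oracles
from sigforge.datatypes import ValidationError
from sigforge.sigscore import activity_score, tertile_stratify, zscore_by_gene
from sigforge.diffexpr import log_transform, normalize_counts
from sigforge.datatypes import GeneSignature
from sigforge.simulate import SimulationSpec, generate_cohort
from sigforge.survival import (
    kaplan_meier,
    logrank_test,
    time_dependent_auc,
    trait_correlation,
)


# ------------------------------------------------------------ Kaplan-Meier


def test_km_toy_curve():
    curve = kaplan_meier([1, 2, 3, 4], [1, 1, 0, 1])
    np.testing.assert_array_equal(curve.event_times, [1, 2, 4])
    np.testing.assert_allclose(curve.survival_prob, [0.75, 0.50, 0.0])
    assert curve.survival_at(0.5) == 1.0
    assert curve.survival_at(2.5) == 0.5


def test_km_all_censored_flat():
    curve = kaplan_meier([3, 5, 9], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(100) == 1.0


def test_km_all_64_six_subject_patterns_match_oracle():
    times = np.array([1.0, 2, 3, 4, 5, 6])
    for pattern in itertools.product([0, 1], repeat=6):
        events = np.array(pattern)
        curve = kaplan_meier(times, events)
        o_t, o_s = oracles.km_product_limit(times, events)
        np.testing.assert_array_equal(curve.event_times, o_t)
        np.testing.assert_allclose(curve.survival_prob, o_s, atol=1e-12)


def test_km_censoring_at_event_time_processed_after_events():
    curve = kaplan_meier([1, 1, 2], [1, 0, 1])
    np.testing.assert_allclose(curve.survival_prob, [2 / 3, 0.0])
    np.testing.assert_array_equal(curve.n_at_risk, [3, 1])


def test_km_duplication_invariance():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 15).round(1)
    e = rng.integers(0, 2, 15)
    a = kaplan_meier(t, e)
    b = kaplan_meier(np.concatenate([t, t]), np.concatenate([e, e]))
    np.testing.assert_allclose(a.survival_prob, b.survival_prob, atol=1e-12)


def test_km_agrees_with_lifelines():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, 40).round(2)
    e = rng.integers(0, 2, 40)
    curve = kaplan_meier(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for et, s in zip(curve.event_times, curve.survival_prob):
        assert kmf.survival_function_at_times(et).iloc[0] == pytest.approx(s, abs=1e-10)


# ---------------------------------------------------------------- log-rank


def test_logrank_identical_groups_null():
    t = [1, 2, 3, 4, 5]
    e = [1, 0, 1, 1, 0]
    res = logrank_test(t, e, t, e)
    assert res.chi2 == pytest.approx(0, abs=1e-12)
    assert res.p == pytest.approx(1, abs=1e-12)


def test_logrank_symmetric_and_scale_invariant():
    rng = np.random.default_rng(2)
    t1, t2 = rng.exponential(5, 20), rng.exponential(9, 25)
    e1, e2 = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
    a = logrank_test(t1, e1, t2, e2)
    b = logrank_test(t2, e2, t1, e1)
    assert a.chi2 == pytest.approx(b.chi2, rel=1e-10)
    c = logrank_test(t1 * 365.25, e1, t2 * 365.25, e2)
    assert a.chi2 == pytest.approx(c.chi2, rel=1e-10)


def test_logrank_matches_risk_table_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n1, n2 = rng.integers(4, 15, 2)
        t1 = rng.integers(1, 10, n1).astype(float)
        t2 = rng.integers(1, 10, n2).astype(float)
        e1 = rng.integers(0, 2, n1)
        e2 = rng.integers(0, 2, n2)
        if e1.sum() + e2.sum() == 0:
            continue
        res = logrank_test(t1, e1, t2, e2)
        assert res.chi2 == pytest.approx(oracles.logrank_chi2(t1, e1, t2, e2), rel=1e-8)


def test_logrank_zero_events_warns_p_one():
    res = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
    assert res.p == 1.0


def test_logrank_power_on_planted_cohorts():
    """Strong planted hazard separates score tertiles most of the time."""
    hits = 0
    n_reps = 40
    for seed in range(n_reps):
        expr, clin, truth = generate_cohort(SimulationSpec(n_patients=60, seed=seed))
        z = zscore_by_gene(log_transform(normalize_counts(expr)))
        sig = GeneSignature("planted", truth.true_up_genes, truth.true_down_genes)
        strata = tertile_stratify(activity_score(z, sig).scores)
        t = clin.table.set_index("patient_id")
        hi, lo = strata.patients("high"), strata.patients("low")
        res = logrank_test(t.loc[hi, "os_time"], t.loc[hi, "os_event"],
                           t.loc[lo, "os_time"], t.loc[lo, "os_event"])
        hits += res.p < 0.05
    assert hits / n_reps >= 0.8


# -------------------------------------------------------------- correlation


def test_pearson_trivial_cases():
    x = np.array([1.0, 2, 3, 5, 8])
    assert trait_correlation(x, x).r == pytest.approx(1.0)
    assert trait_correlation(x, -2 * x + 3).r == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    x = np.array([1.0, 4, 2, 8, 5])
    y = np.array([3.0, 1, 7, 2, 9])
    r = trait_correlation(x, y).r
    manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(manual, abs=1e-12)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValidationError):
        trait_correlation([1, 1, 1], [1, 2, 3])


# --------------------------------------------------------------------- AUC


def test_auc_perfect_separation():
    scores = np.array([5.0, 4, 3, 2, 1, 0])
    times = np.array([1.0, 2, 3, 100, 100, 100])
    events = np.array([1, 1, 1, 0, 0, 0])
    res = time_dependent_auc(scores, times, events, horizon=50)
    assert res.auc == 1.0
    assert res.n_cases == 3 and res.n_controls == 3


def test_auc_no_censoring_equals_rank_auc():
    rng = np.random.default_rng(4)
    for _ in range(10):
        scores = rng.standard_normal(20)
        times = rng.uniform(0, 10, 20)
        events = np.ones(20, dtype=int)
        horizon = 5.0
        case = times <= horizon
        if case.sum() in (0, 20):
            continue
        res = time_dependent_auc(scores, times, events, horizon)
        expected = oracles.rank_auc(scores[case], scores[~case])
        assert res.auc == pytest.approx(expected, abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    scores = rng.standard_normal(50)
    times = rng.exponential(5, 50)
    events = rng.integers(0, 2, 50)
    h = float(np.median(times))
    a = time_dependent_auc(scores, times, events, h).auc
    b = time_dependent_auc(np.exp(scores), times, events, h).auc
    assert a == pytest.approx(b, abs=1e-12)


def test_auc_errors_without_cases_or_controls():
    with pytest.raises(ValidationError, match="horizon"):
        time_dependent_auc([1, 2, 3], [5, 6, 7], [0, 0, 0], horizon=1.0)
    with pytest.raises(ValidationError):
        time_dependent_auc([1, 2, 3], [5, 6, 7], [1, 1, 1], horizon=20.0)


def test_auc_planted_signature_beats_random(demo_cohort):
    _, expr, clin, truth = demo_cohort
    z = zscore_by_gene(log_transform(normalize_counts(expr)))
    t = clin.table.set_index("patient_id")
    planted = GeneSignature("planted", truth.true_up_genes, truth.true_down_genes)
    rng = np.random.default_rng(0)
    others = [g for g in expr.gene_ids if g not in set(planted.genes)]
    pick = list(rng.choice(others, 60, replace=False))
    rand = GeneSignature("random", pick[:30], pick[30:])
    h = 3 * 365.25
    auc_p = time_dependent_auc(activity_score(z, planted).scores.loc[t.index],
                               t["os_time"], t["os_event"], h).auc
    auc_r = time_dependent_auc(activity_score(z, rand).scores.loc[t.index],
                               t["os_time"], t["os_event"], h).auc
    assert auc_p > auc_r
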