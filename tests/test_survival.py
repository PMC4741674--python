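import math

import numpy as np
import pandas as pd
import pytest

from glycotype import (
    km_estimate,
    logrank_test,
    longer_than_threshold_odds,
    odds_ratio,
    os_minus_hps,
    outlive_prediction_odds,
    simulate_cohort,
    stratify,
)
from glycotype.survival import compare_survival_by_group, is_forssman_responder
from oracles import (
    oracle_km,
    oracle_logrank_chi2,
    oracle_odds_ratio,
    permutation_logrank_p,
)


def test_km_no_censoring_equals_empirical_survival():
    curve = km_estimate([1, 2, 3, 4])
    np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
    assert curve.median == 2.0
    assert curve.survival_at(0.5) == 1.0
    assert curve.survival_at(2.5) == 0.5


def test_km_all_censored_stays_at_one():
    curve = km_estimate([3.0, 5.0, 8.0], [False, False, False])
    assert curve.survival_at(100) == 1.0
    assert math.isnan(curve.median)


def test_km_mixed_censoring_matches_hand_unrolled_table():
    times = [2, 3, 3, 5, 6, 7, 7, 9, 11, 14]
    events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
    curve = km_estimate(times, [bool(e) for e in events])
    oracle = oracle_km(times, events)
    assert len(curve.times) == len(oracle)
    for i, (t, at_risk, deaths, s) in enumerate(oracle):
        assert curve.times[i] == t
        assert curve.at_risk[i] == at_risk
        assert curve.n_events[i] == deaths
        assert curve.survival[i] == pytest.approx(s, rel=1e-12)


def test_km_matches_lifelines():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(0)
    times = rng.exponential(10, size=50).round(2) + 0.01
    events = rng.random(50) < 0.7
    curve = km_estimate(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    for t in curve.times:
        assert curve.survival_at(t) == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), rel=1e-9
        )


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_estimate([])
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0])


def test_logrank_identical_groups_is_null():
    data = {"g1": ([1, 2, 3, 4], [True] * 4), "g2": ([1, 2, 3, 4], [True] * 4)}
    cmp = logrank_test(data)
    assert cmp.logrank_chi2 == 0.0
    assert cmp.logrank_p == 1.0


def test_logrank_matches_lifelines():
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(1)
    t1 = rng.exponential(10, 30) + 0.01
    t2 = rng.exponential(16, 25) + 0.01
    e1 = rng.random(30) < 0.8
    e2 = rng.random(25) < 0.8
    cmp = logrank_test({"a": (t1, e1), "b": (t2, e2)})
    ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert cmp.logrank_chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
    assert cmp.logrank_p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_agrees_with_permutation_oracle():
    rng = np.random.default_rng(2)
    t1 = rng.exponential(10, 20) + 0.01
    t2 = rng.exponential(15, 20) + 0.01
    e1 = np.ones(20, bool)
    e2 = np.ones(20, bool)
    cmp = logrank_test({"a": (t1, e1), "b": (t2, e2)})
    p_perm = permutation_logrank_p(t1, e1, t2, e2, n_perm=2000, seed=3)
    se = math.sqrt(max(p_perm * (1 - p_perm), 1e-6) / 2000)
    assert abs(cmp.logrank_p - p_perm) < 3 * se + 0.01


def test_logrank_separated_groups_reject():
    t1 = np.arange(1.0, 21.0)
    t2 = t1 + 200.0
    cmp = logrank_test({"a": (t1, np.ones(20, bool)), "b": (t2, np.ones(20, bool))})
    assert cmp.logrank_p < 1e-6


def test_logrank_symmetric_and_time_scale_invariant():
    rng = np.random.default_rng(4)
    t1 = rng.exponential(10, 15) + 0.01
    t2 = rng.exponential(20, 18) + 0.01
    e1 = rng.random(15) < 0.9
    e2 = rng.random(18) < 0.9
    c12 = logrank_test({"a": (t1, e1), "b": (t2, e2)})
    c21 = logrank_test({"a": (t2, e2), "b": (t1, e1)})
    assert c12.logrank_chi2 == pytest.approx(c21.logrank_chi2, rel=1e-12)
    scaled = logrank_test({"a": (t1 * 12, e1), "b": (t2 * 12, e2)})
    assert scaled.logrank_chi2 == pytest.approx(c12.logrank_chi2, rel=1e-12)


def test_logrank_input_validation():
    with pytest.raises(ValueError):
        logrank_test({"a": ([1.0], [True])})
    with pytest.raises(ValueError):
        logrank_test({"a": ([1.0], [False]), "b": ([2.0], [False])})


def test_odds_ratio_symmetric_table():
    result = odds_ratio([[10, 10], [10, 10]])
    assert result.or_value == 1.0
    assert result.ci_low < 1.0 < result.ci_high


def test_odds_ratio_cross_product_and_ci_closed_form():
    result = odds_ratio([[29, 20], [11, 20]])
    orv, lo, hi, p = oracle_odds_ratio([[29, 20], [11, 20]])
    assert result.or_value == pytest.approx((29 * 20) / (20 * 11), rel=1e-12)
    assert result.or_value == pytest.approx(orv, rel=1e-12)
    assert result.ci_low == pytest.approx(lo, rel=1e-12)
    assert result.ci_high == pytest.approx(hi, rel=1e-12)
    assert result.p == pytest.approx(p, rel=1e-12)
    assert result.ci_low <= result.or_value <= result.ci_high


def test_odds_ratio_haldane_correction_on_zero_cell():
    result = odds_ratio([[5, 0], [3, 4]])
    assert result.corrected
    np.testing.assert_allclose(result.table, [[5.5, 0.5], [3.5, 4.5]])
    assert result.or_value == pytest.approx((5.5 * 4.5) / (0.5 * 3.5), rel=1e-12)


def test_odds_ratio_group_exchange_is_reciprocal():
    a = odds_ratio([[12, 7], [5, 16]])
    b = odds_ratio([[5, 16], [12, 7]])  # rows (groups) exchanged
    assert a.or_value == pytest.approx(1 / b.or_value, rel=1e-12)
    assert a.ci_low == pytest.approx(1 / b.ci_high, rel=1e-12)
    assert a.ci_high == pytest.approx(1 / b.ci_low, rel=1e-12)


def test_odds_ratio_rejects_degenerate_tables():
    with pytest.raises(ValueError):
        odds_ratio([[0, 0], [3, 4]])
    with pytest.raises(ValueError):
        odds_ratio([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        odds_ratio([[-1, 2], [3, 4]])


def _toy_cohort():
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(8)],
            "blood_type": ["O", "AB", "A", "B", "O", "A", "AB", "B"],
            "arm": ["vaccine"] * 8,
            "os_months": [30.0, 21.7, 15.8, 38.0, 27.6, 12.0, 25.0, 40.0],
            "event": [True] * 8,
            "hps_months": [22.5, 23.0, 17.0, 30.0, 20.0, 14.0, 26.0, 29.0],
            "forssman_pre": [10.0, 10.0, 9.5, 11.0, 10.0, 10.0, 10.0, 10.0],
            "forssman_post": [12.0, 11.9, 12.5, 13.5, 10.5, 12.1, 11.0, 14.0],
        }
    ).set_index("patient_id", drop=False)


def test_stratify_pooling_and_forssman_boundary():
    strat = stratify(_toy_cohort())
    by_id = strat.set_index("patient_id")
    assert by_id.loc["p0", "bt_group"] == "B/O"
    assert by_id.loc["p1", "bt_group"] == "A/AB"
    # exactly 4-fold (log2 rise of 2.0) is a responder; just under is not
    assert bool(by_id.loc["p0", "forssman_response"])
    assert not bool(by_id.loc["p1", "forssman_response"])
    assert set(strat["stratum"]) <= {
        "A/AB Fs+", "A/AB Fs-", "B/O Fs+", "B/O Fs-"
    }
    assert is_forssman_responder(10.0, 12.0)
    assert not is_forssman_responder(10.0, 11.9)


def test_stratify_excludes_unknown_types(caplog):
    cohort = _toy_cohort()
    cohort.loc["p0", "blood_type"] = "unclassified"
    with caplog.at_level("WARNING"):
        strat = stratify(cohort)
    assert len(strat) == 7
    assert "excluded 1" in caplog.text


def test_os_minus_hps_subtraction_and_medians():
    result = os_minus_hps(_toy_cohort())
    # p0: 30 - 22.5 = +7.5
    assert result.differences["p0"] == pytest.approx(7.5)
    bo = [30 - 22.5, 38 - 30, 27.6 - 20, 40 - 29]
    assert result.group_medians["B/O"] == pytest.approx(np.median(bo))
    assert 0 < result.t_p <= 1
    assert 0 < result.mannwhitney_p <= 1


def test_os_minus_hps_identical_values_is_null():
    cohort = _toy_cohort()
    cohort["hps_months"] = cohort["os_months"]
    result = os_minus_hps(cohort)
    assert all(d == 0 for d in result.differences)
    assert result.t_p == 1.0


def test_os_minus_hps_sign_recovery_on_simulated_cohorts():
    """The configured vaccine-arm B/O benefit shows up as a positive
    B/O-minus-A/AB median difference in nearly all replicates."""
    rng = np.random.default_rng(5)
    hits = 0
    reps = 60
    for _ in range(reps):
        cohort, _ = simulate_cohort(80, 2, seed=rng, make_profiles=False)
        vac = cohort[cohort["arm"] == "vaccine"].rename(
            columns={"true_blood_type": "blood_type"}
        )
        res = os_minus_hps(vac)
        if res.group_medians["B/O"] > res.group_medians["A/AB"]:
            hits += 1
    assert hits / reps >= 0.95


def test_cohort_level_odds_helpers():
    strat = stratify(_toy_cohort())
    odds, threshold = longer_than_threshold_odds(strat)
    assert threshold == pytest.approx(strat["os_months"].median())
    assert odds.or_value > 0
    pred = outlive_prediction_odds(strat)
    assert pred.or_value > 0


def test_compare_survival_by_group_runs():
    strat = stratify(_toy_cohort())
    cmp = compare_survival_by_group(strat)
    assert set(cmp.medians) == {"A/AB", "B/O"}
    assert 0 < cmp.logrank_p <= 1
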