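"""Endpoint construction, KM/log-rank/Cox machinery against hand oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunomargin.survival import (
    bonferroni,
    build_endpoints,
    correlate,
    cox_multivariable,
    cox_univariable,
    endpoint_table,
    inverse_km_followup,
    km_estimate,
    logrank_test,
    region_comparison,
    screen_univariable,
)
from immunomargin.synthesize import CohortConfig, simulate_outcomes


def hand_logrank_2group(t1, e1, t2, e2):
    """Independent O-E/V tabulation over pooled distinct event times."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O1 = E1 = V = 0.0
    for t in times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (O1 - E1) ** 2 / V
    return chi2


class TestBuildEndpoints:
    def test_recurrence_then_death(self):
        eps = build_endpoints(12.0, 20.0, 20.0)
        assert (eps["TTR"].time, eps["TTR"].event) == (12.0, 1)
        assert (eps["DFS"].time, eps["DFS"].event) == (12.0, 1)
        assert (eps["OS"].time, eps["OS"].event) == (20.0, 1)

    def test_death_without_recurrence_censors_ttr(self):
        eps = build_endpoints(None, 20.0, 20.0)
        assert (eps["TTR"].time, eps["TTR"].event) == (20.0, 0)
        assert (eps["DFS"].time, eps["DFS"].event) == (20.0, 1)
        assert (eps["OS"].time, eps["OS"].event) == (20.0, 1)

    def test_event_free_censors_everything(self):
        eps = build_endpoints(None, None, 36.0)
        for name in ("TTR", "DFS", "OS"):
            assert (eps[name].time, eps[name].event) == (36.0, 0)

    def test_inconsistent_times_rejected(self):
        with pytest.raises(ValueError):
            build_endpoints(40.0, None, 36.0)
        with pytest.raises(ValueError):
            build_endpoints(-1.0, None, 36.0)

    @given(
        st.booleans(),
        st.booleans(),
        st.floats(1.0, 50.0),
        st.floats(1.0, 50.0),
        st.floats(50.0, 120.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_dfs_is_min_of_ttr_and_os(self, has_rec, has_death, t_rec, t_death, fu):
        rec = min(t_rec, t_death if has_death else fu, fu) if has_rec else None
        death = min(t_death, fu) if has_death else None
        eps = build_endpoints(rec, death, fu)
        assert eps["DFS"].time == pytest.approx(min(eps["TTR"].time, eps["OS"].time))
        # idempotence: rebuilding from the same inputs changes nothing
        again = build_endpoints(rec, death, fu)
        assert all(
            (eps[k].time, eps[k].event) == (again[k].time, again[k].event) for k in eps
        )


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3, abs=1e-10)
        assert curve.survival_at(2.0) == pytest.approx(1 / 3, abs=1e-10)
        assert curve.survival_at(3.0) == pytest.approx(0.0, abs=1e-10)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
        assert curve.survival_at(9.0) == pytest.approx(1.0, abs=1e-10)

    def test_single_subject_steps_to_zero(self):
        curve = km_estimate([4.0], [1])
        assert curve.survival_at(3.9) == 1.0
        assert curve.survival_at(4.0) == pytest.approx(0.0, abs=1e-10)

    def test_at_risk_non_increasing(self):
        curve = km_estimate([1.0, 2.0, 2.0, 5.0, 8.0], [1, 0, 1, 1, 0])
        assert (np.diff(curve.at_risk) <= 0).all()


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [2.0, 4.0, 6.0]
        e = [1, 0, 1]
        stat, p, flags = logrank_test({"a": (t, e), "b": (t, e)})
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_tabulation(self):
        t1, e1 = [1.0, 3.0, 5.0, 7.0], [1, 1, 0, 1]
        t2, e2 = [2.0, 3.0, 6.0, 9.0], [1, 0, 1, 0]
        stat, p, flags = logrank_test({"a": (t1, e1), "b": (t2, e2)})
        assert not flags
        assert stat == pytest.approx(hand_logrank_2group(t1, e1, t2, e2), abs=1e-10)

    def test_no_events_flagged(self):
        stat, p, flags = logrank_test({"a": ([1.0], [0]), "b": ([2.0], [0])})
        assert np.isnan(stat)
        assert flags


class TestCox:
    def _cohort(self, n, log_hr, seed, rho=0.0):
        cfg = CohortConfig(
            n_patients=n,
            log_hr_recurrence={"group_high": log_hr},
            event_correlation=rho,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        group = rng.integers(0, 2, size=n)
        age = rng.normal(69, 8, size=n)
        tnm = rng.integers(1, 3, size=n)
        out = simulate_outcomes(group, age, tnm, cfg, rng)
        eps = endpoint_table(out)
        return pd.DataFrame(
            {
                "time": eps["TTR_time"],
                "event": eps["TTR_event"],
                "factor": np.where(group == 1, "high", "low"),
                "age": age,
                "tnm_stage": tnm,
            }
        )

    def test_null_effect_recovered_within_3_se(self):
        df = self._cohort(400, 0.0, seed=21)
        res = cox_univariable(df["time"], df["event"], df["factor"], term="group")
        assert res.ok
        eff = res.levels[0]
        log_hr = math.log(eff.hazard_ratio)
        se = (math.log(eff.ci_high) - math.log(eff.ci_low)) / (2 * 1.959963984540054)
        assert abs(log_hr) < 3 * se

    def test_empty_event_level_flagged(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "event": [1, 1, 0, 0, 0, 0],
                "factor": ["low", "low", "high", "high", "high", "high"],
            }
        )
        res = cox_univariable(df["time"], df["event"], df["factor"])
        assert not res.ok
        assert any("no events" in f for f in res.flags)

    def test_three_level_factor_reports_type3(self):
        rng = np.random.default_rng(4)
        n = 300
        level = rng.choice(["low", "intermediate", "high"], size=n)
        rate = np.where(level == "low", 0.05, np.where(level == "intermediate", 0.03, 0.01))
        t = rng.exponential(1 / rate)
        df = pd.DataFrame({"time": t, "event": np.ones(n, dtype=int), "factor": level})
        res = cox_univariable(df["time"], df["event"], df["factor"])
        assert res.ok
        assert {e.level for e in res.levels} == {"intermediate vs low", "high vs low"}
        assert res.type3_p < 0.01

    def test_adjustment_moves_estimate_toward_truth(self):
        # Planted confounding: the high-immune group is also older, and age
        # raises the recurrence hazard, so the crude HR understates the
        # protective effect; adjusting for age must move it back.
        n, true_log_hr = 800, math.log(0.5)
        rng = np.random.default_rng(8)
        group = rng.integers(0, 2, size=n)
        age = 69 + 8 * group + rng.normal(0, 4, size=n)
        tnm = rng.integers(1, 3, size=n)
        cfg = CohortConfig(
            n_patients=n,
            log_hr_recurrence={"group_high": true_log_hr, "age_per_decade": 0.9},
            event_correlation=0.0,
            seed=8,
        )
        out = simulate_outcomes(group, age, tnm, cfg, rng)
        eps = endpoint_table(out)
        df = pd.DataFrame(
            {
                "TTR_time": eps["TTR_time"],
                "TTR_event": eps["TTR_event"],
                "feature": np.where(group == 1, "high", "low"),
                "age": age,
                "tnm_stage": tnm.astype(float),
            }
        )
        crude = cox_univariable(df["TTR_time"], df["TTR_event"], df["feature"])
        adjusted = cox_multivariable(df, "TTR_time", "TTR_event", "feature")
        assert crude.ok and adjusted.ok
        crude_err = abs(math.log(crude.levels[0].hazard_ratio) - true_log_hr)
        adj_err = abs(math.log(adjusted.levels[0].hazard_ratio) - true_log_hr)
        assert adj_err < crude_err

    def test_screening_excludes_null_features(self):
        df = self._cohort(300, math.log(0.3), seed=31)
        rng = np.random.default_rng(0)
        df["noise"] = rng.choice(["low", "high"], size=len(df))
        kept = screen_univariable(df, "time", "event", ["factor", "noise"])
        assert "factor" in kept
        assert "noise" not in kept


class TestInverseKM:
    def test_all_censored_at_50(self):
        med, ci, flags = inverse_km_followup([50.0] * 5, [0] * 5)
        assert med == pytest.approx(50.0)
        assert not flags

    def test_all_deaths_median_not_reached(self):
        med, ci, flags = inverse_km_followup([10.0, 20.0, 30.0], [1, 1, 1])
        assert np.isnan(med)
        assert flags

    def test_mixed_toy_set_matches_hand_reverse_km(self):
        # Flipped indicators: censorings at 20 and 40 become the events.
        # Reverse-KM: S(20) = 2/3 (wait, n at 20 is 3) -> drops below 0.5 at 40.
        times = [10.0, 20.0, 30.0, 40.0]
        events = [1, 0, 1, 0]
        med, ci, flags = inverse_km_followup(times, events)
        assert med == pytest.approx(40.0, abs=1e-10)


class TestRegionComparison:
    def test_identical_columns_accept_null(self):
        qa = pd.DataFrame({"innM": [1.0, 2, 3, 4, 5, 6], "outM": [1.0, 2, 3, 4, 5, 6]})
        rep = region_comparison(qa)
        assert rep["friedman_statistic"] == 0.0
        assert rep["friedman_p"] == 1.0
        assert rep["pairwise"][("innM", "outM")]["p_bonferroni"] == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni(0.02, 10) == pytest.approx(0.2)
        assert bonferroni(0.3, 10) == 1.0

    def test_few_pairs_flagged_low_power(self):
        qa = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 3, 4]})
        rep = region_comparison(qa)
        assert any("low power" in f for f in rep["flags"])

    def test_gradient_detected(self, rng):
        n = 40
        inn = rng.gamma(4.0, 50.0, size=n)
        qa = pd.DataFrame({"TC": inn * 0.5, "innM": inn, "outM": inn * 3.0})
        rep = region_comparison(qa)
        assert rep["friedman_p"] < 0.001
        assert rep["pairwise"][("innM", "outM")]["p_bonferroni"] < 0.001


class TestSpearman:
    def test_monotone_pair_is_perfect(self):
        rho, p, flags = correlate([1.0, 2, 3, 4, 5], [10.0, 20, 40, 80, 100])
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # Ranks: a -> 1..5; b -> 2,1,4,3,5; rho = 1 - 6*sum(d^2)/(n(n^2-1)).
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [5.0, 2.0, 30.0, 10.0, 100.0]
        d2 = sum((ra - rb) ** 2 for ra, rb in zip([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))
        expected = 1 - 6 * d2 / (5 * 24)
        rho, p, flags = correlate(a, b)
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_constant_input_flagged(self):
        rho, p, flags = correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho)
        assert flags

    def test_independent_pairs_center_at_zero(self, rng):
        rhos = []
        for _ in range(100):
            rho, _, _ = correlate(rng.normal(size=20), rng.normal(size=20))
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 3 * np.std(rhos) / 10
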