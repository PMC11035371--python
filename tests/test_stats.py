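"""Survival analysis, group tests and censoring-aware recovery summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from ictalab.detect import SeizureEvent
from ictalab.stats import (gehan_breslow_wilcoxon, gehan_scores, km_estimate,
                           one_way_anova, proportion_compare, recovery_table,
                           seizure_metrics, two_way_anova, unpaired_t)


class TestSeizureMetrics:
    def test_counts_and_minutes(self):
        events = [(100.0, 130.0), (200.0, 260.0), (300.0, 390.0)]
        m = seizure_metrics(events, injection_time=0.0, animal_id="a")
        assert m.count == 3
        assert m.mean_duration_min == pytest.approx(1.0)

    def test_latency_from_injection(self):
        m = seizure_metrics([(220.0, 260.0)], injection_time=100.0)
        assert m.onset_latency_min == pytest.approx(2.0)

    def test_no_events_flagged(self):
        m = seizure_metrics([], injection_time=0.0)
        assert m.count == 0
        assert np.isnan(m.mean_duration_min) and np.isnan(m.onset_latency_min)

    def test_pre_injection_events_excluded(self):
        m = seizure_metrics([(50.0, 60.0), (200.0, 230.0)],
                            injection_time=100.0)
        assert m.count == 1

    def test_accepts_seizure_events(self):
        ev = SeizureEvent("ch0", 160.0, 220.0, 1.0, 8.0, 7.0)
        m = seizure_metrics([ev], injection_time=100.0)
        assert m.mean_duration_min == pytest.approx(1.0)


class TestKaplanMeier:
    def test_closed_form_no_censoring(self):
        km = km_estimate([30.0, 60.0, 90.0], [True, True, True])
        s = dict(zip(km.time, km.survival))
        assert s[30.0] == pytest.approx(2 / 3)
        assert s[60.0] == pytest.approx(1 / 3)
        assert s[90.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_estimate([30.0, 60.0], [False, False])
        assert (km.survival == 1.0).all()

    def test_tied_events_single_step(self):
        km = km_estimate([30.0, 30.0, 90.0], [True, True, True])
        s = dict(zip(km.time, km.survival))
        assert s[30.0] == pytest.approx(1 / 3)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=50)
        km = km_estimate(t, np.ones(50, bool))
        emp = 1.0 - np.arange(1, 51) / 50
        np.testing.assert_allclose(km.survival[1:], np.sort(emp)[::-1],
                                   atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestGehanBreslowWilcoxon:
    def test_identical_groups_null(self):
        t = [30.0, 60.0, 90.0, 120.0]
        e = [True] * 4
        r = gehan_breslow_wilcoxon(t, e, t, e)
        assert r["statistic"] == pytest.approx(0.0)
        assert r["p"] == pytest.approx(1.0)

    def test_separated_groups_match_permutation(self):
        # all of A at 30 min, all of B at 300 min: asymptotic p within
        # 0.01 of the (near-exhaustive at n=5+5) permutation p
        a_t, b_t = [30.0] * 5, [300.0] * 5
        e = [True] * 5
        r = gehan_breslow_wilcoxon(a_t, e, b_t, e, n_permutations=100_000,
                                   seed=0)
        assert abs(r["p"] - r["p_permutation"]) <= 0.01

    def test_censoring_after_last_event_inert(self):
        a_t, a_e = [30.0, 60.0, 90.0], [True, True, True]
        b_t, b_e = [60.0, 120.0, 150.0], [True, True, True]
        r1 = gehan_breslow_wilcoxon(a_t, a_e, b_t, b_e)
        r2 = gehan_breslow_wilcoxon(a_t, a_e, b_t + [400.0],
                                    b_e + [False])
        # the late-censored animal outlives every event, so each of A's
        # (early) scores drops by exactly one
        assert r1["w"] - r2["w"] == pytest.approx(len(a_t))
        # the added censored animal contributes no discordant pair beyond
        # outliving every event, so significance direction is unchanged
        assert (r1["p"] < 0.5) == (r2["p"] < 0.5)

    def test_label_symmetry(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(10, 8), rng.exponential(20, 8)
        ea = rng.random(8) > 0.2
        eb = rng.random(8) > 0.2
        r1 = gehan_breslow_wilcoxon(ta, ea, tb, eb)
        r2 = gehan_breslow_wilcoxon(tb, eb, ta, ea)
        assert r1["p"] == pytest.approx(r2["p"])
        assert r1["statistic"] == pytest.approx(r2["statistic"])

    def test_cross_checked_against_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        ta = rng.exponential(60, 12)
        tb = rng.exponential(180, 12)
        ea = np.ones(12, bool)
        eb = tb < 240
        tb = np.minimum(tb, 240)
        r = gehan_breslow_wilcoxon(ta, ea, tb, eb)
        lr = logrank_test(ta, tb, ea, eb, weightings="wilcoxon")
        # same family of tests with different variance estimators: demand
        # close agreement, not identity
        assert r["p"] == pytest.approx(lr.p_value, abs=0.02)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            gehan_breslow_wilcoxon([1.0, 2.0], [False, False],
                                   [3.0, 4.0], [False, False])

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 20)
        d = rng.random(20) > 0.3
        assert gehan_scores(t, d).sum() == 0


class TestProportions:
    def test_percentages(self):
        r = proportion_compare(8, 13, 3, 14)
        assert round(r["proportion_a"], 1) == 61.5
        assert round(r["proportion_b"], 1) == 21.4

    def test_equal_zero_proportions(self):
        assert proportion_compare(0, 10, 0, 10)["p"] == pytest.approx(1.0)

    def test_total_separation_hypergeometric(self):
        # 10/10 vs 0/10: two-sided Fisher p = 2 / C(20,10) = 1/92378
        r = proportion_compare(10, 10, 0, 10)
        assert r["p"] == pytest.approx(2 / 184_756, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            proportion_compare(0, 0, 1, 10)


class TestGroupTests:
    def test_identical_samples_null_t(self):
        r = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r["t"] == pytest.approx(0.0)
        assert r["p"] == pytest.approx(1.0)

    def test_anova_hand_computed_f(self):
        # groups (1,2,3), (2,3,4), (4,5,6): SSB=14 (df 2), SSW=6 (df 6)
        # => F = 7 exactly
        df = pd.DataFrame({
            "value": [1, 2, 3, 2, 3, 4, 4, 5, 6],
            "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        })
        r = one_way_anova(df)
        assert r["F"] == pytest.approx(7.0, abs=1e-10)
        assert r["p"] == pytest.approx(spstats.f.sf(7.0, 2, 6), abs=1e-12)
        assert len(r["tukey"]) == 3

    def test_two_way_balanced_null_interaction(self):
        # additive construction: interaction sum of squares ~ 0
        rows = []
        for a, va in (("t1", 0.0), ("t2", 5.0)):
            for b, vb in (("ipsi", 0.0), ("contra", 2.0)):
                for r in range(4):
                    rows.append((a, b, va + vb + 0.1 * r))
        df = pd.DataFrame(rows, columns=["treatment", "hemisphere", "value"])
        table = two_way_anova(df)
        inter = [i for i in table.index if ":" in i][0]
        assert table.loc[inter, "sum_sq"] == pytest.approx(0.0, abs=1e-12)
        mains = [i for i in table.index
                 if "C(" in i and ":" not in i]
        assert all(table.loc[m, "PR(>F)"] < 1e-6 for m in mains)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(pd.DataFrame({"value": [1.0, 2.0],
                                        "group": ["a", "a"]}))


class TestRecoveryTable:
    def test_all_censored_group_at_cap(self):
        df = pd.DataFrame({
            "group": ["drug"] * 7 + ["control"] * 5,
            "time_min": [60.0] * 7 + [10.0, 12.0, 8.0, 11.0, 9.0],
            "censored": [True] * 7 + [False] * 5,
        })
        r = recovery_table(df, cap_min=60.0)
        drug = r["summary"].set_index("group").loc["drug"]
        assert drug["mean_min"] == pytest.approx(60.00)
        assert drug["sem_min"] == 0.0
        assert drug["censored_fraction"] == 1.0

    def test_mixed_censoring(self):
        df = pd.DataFrame({"group": ["g"] * 3,
                           "time_min": [10.0, 20.0, 60.0],
                           "censored": [False, False, True]})
        r = recovery_table(df)
        row = r["summary"].iloc[0]
        assert row["mean_min"] == pytest.approx(30.0)
        assert row["censored_fraction"] == pytest.approx(1 / 3)

    def test_time_beyond_cap_rejected(self):
        df = pd.DataFrame({"group": ["g"], "time_min": [65.0],
                           "censored": [False]})
        with pytest.raises(ValueError):
            recovery_table(df)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            recovery_table(pd.DataFrame(columns=["group", "time_min",
                                                 "censored"]))
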