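"""Inferential layer: Levene gate, t variants, tau-c, power, game tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import dyadphys as dp
from dyadphys import reference
from dyadphys.errors import DegenerateError, InsufficientDataError
from dyadphys.stats import _cohens_d
from dyadphys.stats import TestVariant as Variant


class TestLevene:
    def test_identical_deviation_patterns(self):
        w, p = dp.levene_test([1, 2, 3], [4, 5, 6])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_heteroscedastic_groups_detected(self):
        w, p = dp.levene_test([0, 0, 0, 0], [-10, 10, -10, 10])
        assert w > 50 and p < 0.01

    def test_matches_anova_on_absolute_deviations(self):
        """Oracle: one-way ANOVA F on |x - group mean| computed directly."""
        a, b = [1.0, 2.0, 3.0, 4.0], [-10.0, 10.0, -10.0, 10.0, 5.0]
        w, p = dp.levene_test(a, b)
        dev_a = np.abs(np.asarray(a) - np.mean(a))
        dev_b = np.abs(np.asarray(b) - np.mean(b))
        f, p_ref = sps.f_oneway(dev_a, dev_b)
        assert w == pytest.approx(f)
        assert p == pytest.approx(p_ref)

    def test_scale_invariance_of_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 3, 10)
        _, p1 = dp.levene_test(a, b)
        _, p2 = dp.levene_test(5.0 * a, 5.0 * b)
        assert p1 == pytest.approx(p2)


class TestTTests:
    def test_identical_groups(self):
        res = dp.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", [Variant.POOLED, Variant.WELCH])
    def test_matches_scipy(self, variant):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 2, 17)
        res = dp.two_sample_t(a, b, variant=variant)
        ref = sps.ttest_ind(a, b, equal_var=(variant is Variant.POOLED))
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.df == pytest.approx(ref.df)

    def test_welch_from_printed_heart_rate_summary(self):
        res = dp.t_from_summary(1.169537, 0.282227, 14,
                                1.492253, 0.514155, 14,
                                variant=Variant.WELCH)
        assert res.t_statistic == pytest.approx(-2.059, abs=0.001)
        assert res.std_error == pytest.approx(0.1567, abs=0.0001)
        assert res.mean_difference == pytest.approx(-0.3227, abs=0.0001)

    def test_summary_equals_raw_data_route(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 14)
        raw = dp.two_sample_t(a, b, variant=Variant.WELCH)
        summ = dp.t_from_summary(a.mean(), a.std(ddof=1), a.size,
                                 b.mean(), b.std(ddof=1), b.size,
                                 variant=Variant.WELCH)
        assert raw.t_statistic == pytest.approx(summ.t_statistic, rel=1e-12)
        assert raw.df == pytest.approx(summ.df, rel=1e-12)

    def test_equal_sd_equal_n_welch_student_identity(self):
        res_w = dp.t_from_summary(1.0, 0.5, 14, 1.4, 0.5, 14,
                                  variant=Variant.WELCH)
        res_p = dp.t_from_summary(1.0, 0.5, 14, 1.4, 0.5, 14,
                                  variant=Variant.POOLED)
        assert res_w.t_statistic == pytest.approx(res_p.t_statistic, rel=1e-12)
        assert res_w.df == pytest.approx(26.0)  # Satterthwaite closed form

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateError):
            dp.two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])


class TestDecisionsAndTauC:
    def test_trust_tables_expand_to_cohort(self):
        pc = dp.encode_decisions(reference.TRUST_FREQUENCIES["PC"], 14)
        assert sorted(pc) == [500] + [1000] * 7 + [1500] * 4 + [2000] * 2

    def test_reciprocity_tables_expand(self):
        ic = dp.encode_decisions(reference.RECIPROCITY_FREQUENCIES["IC"], 14)
        assert sorted(ic) == [0.25] * 3 + [0.5] * 9 + [0.75] * 2

    def test_empty_table(self):
        assert dp.encode_decisions({}) == []

    def test_frequency_sum_mismatch(self):
        with pytest.raises(DegenerateError):
            dp.encode_decisions({100: 3}, expected_n=14)

    def test_tau_c_perfect_concordance(self):
        tau, _ = dp.kendall_tau_c([[5, 0], [0, 5]])
        assert tau == pytest.approx(1.0)

    def test_tau_c_independence(self):
        tau, p = dp.kendall_tau_c([[5, 5], [5, 5]])
        assert tau == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @staticmethod
    def brute_force_tau_c(table):
        """O(n^2) enumeration over all subject pairs."""
        table = np.asarray(table)
        subjects = [(i, j) for i in range(table.shape[0])
                    for j in range(table.shape[1])
                    for _ in range(int(table[i, j]))]
        conc = disc = 0
        for a in range(len(subjects)):
            for b in range(a + 1, len(subjects)):
                (r1, c1), (r2, c2) = subjects[a], subjects[b]
                prod = (r1 - r2) * (c1 - c2)
                conc += prod > 0
                disc += prod < 0
        n, m = len(subjects), min(table.shape)
        return 2.0 * m * (conc - disc) / (n ** 2 * (m - 1))

    @given(st.lists(st.lists(st.integers(0, 6), min_size=2, max_size=4),
                    min_size=2, max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_tau_c_matches_brute_force(self, rows):
        width = len(rows[0])
        table = np.asarray([r[:width] + [0] * (width - len(r)) for r in rows])
        if table.sum() < 4:
            return
        tau, _ = dp.kendall_tau_c(table)
        assert tau == pytest.approx(self.brute_force_tau_c(table), abs=1e-12)
        assert -1.0 <= tau <= 1.0

    def test_tau_c_sign_flips_with_axis_reversal(self):
        table = np.asarray([[6, 1, 0], [2, 3, 2], [0, 2, 5]])
        tau, _ = dp.kendall_tau_c(table)
        tau_rev, _ = dp.kendall_tau_c(table[::-1])
        assert tau == pytest.approx(-tau_rev)

    def test_tau_c_degenerate_table(self):
        with pytest.raises(DegenerateError):
            dp.kendall_tau_c([[3, 4]])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert dp.achieved_power(0.0, 14, 14, 0.05) == pytest.approx(0.05,
                                                                     abs=1e-6)

    def test_huge_effect_saturates(self):
        assert dp.achieved_power(10.0, 14, 14, 0.05) > 0.999999

    def test_matches_monte_carlo_oracle(self):
        # frozen from 1e5 simulated two-sample t-tests at d=1, n=14/14:
        # rejection rate 0.7204 (SE 0.0014)
        assert dp.achieved_power(1.0, 14, 14, 0.05) == pytest.approx(0.7204,
                                                                     abs=0.005)


class TestCompareConditions:
    def features_at_reference(self, seed=0):
        cfg = dp.SynthesisConfig(seed=seed)
        rng = np.random.default_rng(seed)
        rows = []
        for cond in ("PC", "IC"):
            for i, t in enumerate(dp.draw_cohort_targets(cfg, cond, 14, rng)):
                rows.append({"subject_id": f"{cond}{i}", "condition": cond,
                             "role": "proposer", **t})
        return pd.DataFrame(rows)

    def test_game_tests_reproduce_printed_statistics(self):
        games = dp.reference_game_tests()
        assert games["trust"].t_statistic == pytest.approx(0.577, abs=0.001)
        assert games["trust"].df == 26
        assert games["reciprocity"].t_statistic == pytest.approx(2.096,
                                                                 abs=0.001)

    def test_report_shape_and_gating(self):
        feats = self.features_at_reference()
        dec_rows = []
        for cond in ("PC", "IC"):
            for v in dp.encode_decisions(reference.TRUST_FREQUENCIES[cond]):
                dec_rows.append({"condition": cond, "amount_sent": v,
                                 "fraction_returned": None})
            for v in dp.encode_decisions(
                    reference.RECIPROCITY_FREQUENCIES[cond]):
                dec_rows.append({"condition": cond, "amount_sent": None,
                                 "fraction_returned": v})
        report = dp.compare_conditions(feats, pd.DataFrame(dec_rows))
        assert list(report["measure"]) == list(reference.INDEX_NAMES) + \
            ["trust", "reciprocity"]
        gated = report[report["measure"].isin(reference.INDEX_NAMES)]
        assert ((gated["variant"] == "WELCH") ==
                (gated["levene_p"] < 0.05)).all()
        trust = report[report["measure"] == "trust"].iloc[0]
        assert trust["variant"] == "POOLED" and trust["df"] == 26

    def test_single_condition_refused(self):
        feats = self.features_at_reference()
        with pytest.raises(InsufficientDataError):
            dp.compare_conditions(feats[feats.condition == "PC"])

    def test_model_results_summary(self):
        model = dp.ConditionComparison(self.features_at_reference())
        results = model.fit()
        text = results.summary()
        assert "heart_rate" in text and "variant" in text
        res = results["heart_rate"]
        assert np.isfinite(res.t_statistic)
        assert 0 <= res.power <= 1

    def test_moment_matched_cohort_reproduces_table_t_values(self):
        """With sample moments pinned to the printed descriptives, the
        Welch t per measure equals the published between-condition test."""
        feats = self.features_at_reference(seed=4)
        report = dp.compare_conditions(feats)
        ref = {"slow_alpha": -2.130, "alpha_asymmetry": -2.225,
               "lf_hf": -1.798}
        for m, t_ref in ref.items():
            row = report[report["measure"] == m].iloc[0]
            res = dp.t_from_summary(
                *reference.INDEX_STATS[m]["PC"], 14,
                *reference.INDEX_STATS[m]["IC"], 14,
                variant=Variant(row["variant"]))
            assert row["t"] == pytest.approx(res.t_statistic, abs=0.02)
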