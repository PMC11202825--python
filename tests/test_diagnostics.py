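import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from duravol.cohort_sim import GroupDistributionSpec, default_group_specs, sample_cohort
from duravol.diagnostics import (auc_closed_form, auc_empirical, evaluate_table2,
                                 mcnemar, roc_curve, table2_frame, welch_t,
                                 youden_cutoff)


def brute_force_auc(cases, controls):
    """Independent oracle: concordant-pair counting with ties at 1/2."""
    cases, controls = np.asarray(cases), np.asarray(controls)
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestWelchT:
    def test_identical_groups(self):
        g = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g.t == pytest.approx(0.0)
        assert g.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        g = welch_t([1, 2, 3], [4, 5, 6])
        assert g.t == pytest.approx(-3.674, abs=1e-3)
        assert g.p == pytest.approx(0.0213, abs=1e-3)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_power_on_simulated_s1_volumes(self):
        """S1 dural volumes at the default group distributions separate
        at p < 0.001 in at least 95% of 200 simulated cohorts of 63/81."""
        mfs, non = default_group_specs()
        sm = GroupDistributionSpec(group="MFS",
                                   variables={"v": mfs.variables["dural_volume_S1"]})
        sn = GroupDistributionSpec(group="nonMFS",
                                   variables={"v": non.variables["dural_volume_S1"]})
        hits = 0
        for i in range(200):
            c = sample_cohort(sm, sn, 63, 81, seed=5000 + i).table
            g = c["group"] == "MFS"
            if welch_t(c.loc[g, "v"], c.loc[~g, "v"]).p < 0.001:
                hits += 1
        assert hits >= 190


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        est = auc_empirical([3, 4], [1, 2])
        assert est.auc == 1.0
        assert est.ci_low <= est.auc <= est.ci_high

    def test_all_ties_give_half(self):
        assert auc_empirical([0.3, 0.1], [0.2, 0.2]).auc == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            auc_empirical([], [1.0])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 120)), int(rng.integers(2, 120))
        cases = np.round(rng.normal(0.5, 1.0, m), 1)  # rounding forces ties
        controls = np.round(rng.normal(0.0, 1.0, n), 1)
        est = auc_empirical(cases, controls)
        assert est.auc == pytest.approx(brute_force_auc(cases, controls), abs=1e-12)

    def test_delong_ci_covers_true_auc_at_nominal_rate(self):
        """Over 1000 simulated 63/81 cohorts from a known lognormal model,
        the 95% DeLong interval contains the model AUC 93-97% of the time."""
        mfs, non = default_group_specs()
        m1, s1 = mfs.variables["dsvr_L4"]
        m0, s0 = non.variables["dsvr_L4"]
        target = auc_closed_form(m1, s1, m0, s0, family="lognormal")
        sm = GroupDistributionSpec(group="MFS", variables={"v": (m1, s1)})
        sn = GroupDistributionSpec(group="nonMFS", variables={"v": (m0, s0)})
        cover = 0
        for i in range(1000):
            c = sample_cohort(sm, sn, 63, 81, seed=20_000 + i).table
            g = (c["group"] == "MFS").to_numpy()
            v = c["v"].to_numpy()
            est = auc_empirical(v[g], v[~g])
            cover += est.ci_low <= target <= est.ci_high
        assert 930 <= cover <= 970

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(0)
        roc = roc_curve(rng.normal(1, 1, 50), rng.normal(0, 1, 60))
        assert np.all(np.diff(roc.sensitivity) >= 0)  # thresholds descend
        assert np.all(np.diff(roc.specificity) <= 0)


class TestClosedFormAuc:
    def test_binormal_s1_volume_ratio(self):
        assert auc_closed_form(0.41, 0.28, 0.14, 0.06, "normal") \
            == pytest.approx(0.827, abs=1e-3)

    def test_equal_distributions_give_half(self):
        assert auc_closed_form(1.0, 0.5, 1.0, 0.5, "normal") == 0.5
        assert auc_closed_form(1.0, 0.5, 1.0, 0.5, "lognormal") == 0.5

    @given(st.floats(0.1, 3.0), st.floats(0.05, 1.0), st.floats(0.1, 3.0),
           st.floats(0.05, 1.0))
    def test_group_swap_symmetry(self, m1, s1, m0, s0):
        for fam in ("normal", "lognormal"):
            a = auc_closed_form(m1, s1, m0, s0, fam)
            b = auc_closed_form(m0, s0, m1, s1, fam)
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            auc_closed_form(1, 1, 1, 1, "gamma")

    def test_matches_large_sample_empirical(self):
        """The lognormal closed form agrees with the empirical AUC of a
        large sample drawn from the same model."""
        rng = np.random.default_rng(3)
        from duravol.cohort_sim import lognormal_params
        mu1, sg1 = lognormal_params(0.41, 0.28)
        mu0, sg0 = lognormal_params(0.14, 0.06)
        cases = rng.lognormal(mu1, sg1, 40_000)
        controls = rng.lognormal(mu0, sg0, 40_000)
        emp = auc_empirical(cases, controls).auc
        assert emp == pytest.approx(auc_closed_form(0.41, 0.28, 0.14, 0.06, "lognormal"),
                                    abs=0.005)


class TestYouden:
    def test_exhaustive_scan_example(self):
        cut = youden_cutoff([2, 3, 4], [1, 2])
        assert cut.cutoff == 3
        assert cut.sensitivity == pytest.approx(2 / 3)
        assert cut.specificity == 1.0
        assert cut.youden_j == pytest.approx(2 / 3)
        assert cut.youden_j == pytest.approx(cut.sensitivity + cut.specificity - 1)

    def test_perfect_separation_j_one(self):
        assert youden_cutoff([10, 11], [1, 2]).youden_j == pytest.approx(1.0)

    def test_identical_single_value_groups_j_zero(self):
        assert youden_cutoff([5.0, 5.0], [5.0, 5.0]).youden_j == pytest.approx(0.0)

    def test_ppv_npv_from_sample_prevalence(self):
        cut = youden_cutoff([2, 3, 4], [1, 2])
        assert cut.ppv == pytest.approx(1.0)  # 2 TP, 0 FP at cutoff 3
        assert cut.npv == pytest.approx(2 / 3)  # 2 TN, 1 FN


class TestMcNemar:
    def test_exact_binomial_example(self):
        res = mcnemar(10, 2)
        assert res.p == pytest.approx(2 * (1 + 12 + 66) / 4096, abs=1e-12)

    def test_symmetric_discordance_p_one(self):
        assert mcnemar(7, 7).p == 1.0
        assert mcnemar(0, 0).p == 1.0

    def test_one_sided_discordance(self):
        assert mcnemar(8, 0).p == pytest.approx(2 / 256, abs=1e-12)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in ((10, 2), (5, 5), (0, 3), (17, 9)):
            table = [[0, b], [c, 0]]
            ref = sm_mcnemar(table, exact=True)
            assert mcnemar(b, c).p == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_chi2_with_continuity_correction(self):
        res = mcnemar(10, 2, method="chi2_cc")
        assert res.statistic == pytest.approx((abs(10 - 2) - 1) ** 2 / 12)
        assert 0 < res.p < 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 2)


class TestEvaluateTable2:
    @pytest.fixture(scope="class")
    def cohort(self):
        mfs, non = default_group_specs()
        return sample_cohort(mfs, non, 63, 81, seed=77)

    def test_report_has_all_levels(self, cohort):
        res = evaluate_table2(cohort)
        assert set(res) == {"L1", "L2", "L3", "L4", "L5", "S1"}
        assert "auc_dsvr" not in res["L1"]  # diameter-only levels
        assert "auc_dsvr" in res["S1"] and "mcnemar" in res["S1"]

    def test_rank_invariance_under_monotone_transform(self, cohort):
        res = evaluate_table2(cohort)
        warped = cohort.table.copy()
        for col in warped.columns:
            if col.startswith(("dsvr_", "dsdr_")):
                warped[col] = np.exp(3.0 * warped[col])
        res_w = evaluate_table2(warped)
        for lvl in res:
            for key in ("auc_dsvr", "auc_dsdr"):
                if key in res[lvl]:
                    assert res_w[lvl][key].auc == pytest.approx(res[lvl][key].auc,
                                                                abs=1e-12)
            if "mcnemar" in res[lvl]:
                assert res_w[lvl]["mcnemar"].p == pytest.approx(res[lvl]["mcnemar"].p)

    def test_single_level_cohort_restricted_output(self, cohort):
        sub = cohort.table[["patient_id", "group", "dsvr_S1", "dsdr_S1"]]
        res = evaluate_table2(sub)
        assert set(res) == {"S1"}

    def test_missing_columns_rejected(self, cohort):
        with pytest.raises(ValueError, match="dsvr"):
            evaluate_table2(cohort.table[["patient_id", "group", "height"]])

    def test_single_group_rejected(self, cohort):
        sub = cohort.table[cohort.table["group"] == "MFS"]
        with pytest.raises(ValueError, match="both groups"):
            evaluate_table2(sub)

    def test_frame_report_shape(self, cohort):
        frame = table2_frame(evaluate_table2(cohort))
        assert list(frame["level"]) == ["L1", "L2", "L3", "L4", "L5", "S1"]
        assert frame["auc_dsdr"].between(0, 1).all()
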