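"""Survival machinery: dichotomization, KM, log-rank, HR, Welch comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemoscreen.clinical import (
    ClinicalCohort,
    compare_responders,
    hazard_ratio,
    km_estimate,
    logrank_test,
    median_dichotomize,
    read_cohort,
    validate_cohort,
    welch_t,
    write_cohort,
    zscore,
)
from chemoscreen.simulate import SyntheticClinicalConfig, generate_clinical_cohort
from helpers_oracles import km_table, logrank_oe, mh_hazard_ratio, welch_formulas


def cohort_from(expr, time, event, chemo, response=None, cohort_id="C"):
    data = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(expr))],
            "expr": expr,
            "time": time,
            "event": event,
            "chemo": chemo,
        }
    )
    if response is not None:
        data["response"] = response
    return ClinicalCohort(cohort_id=cohort_id, data=data)


class TestMedianDichotomize:
    def test_even_split_without_ties(self):
        labels = median_dichotomize([1.0, 2.0, 3.0, 4.0])
        assert list(labels) == ["LOW", "LOW", "HIGH", "HIGH"]

    def test_ties_at_the_median_fall_low(self):
        labels = median_dichotomize([1.0, 2.0, 2.0, 3.0])
        assert (labels == "HIGH").sum() == 1 and (labels == "LOW").sum() == 3

    def test_too_few_patients_is_an_error(self):
        with pytest.raises(ValueError):
            median_dichotomize([1.0, 2.0, 3.0])

    def test_constant_expression_is_an_error(self):
        with pytest.raises(ValueError):
            median_dichotomize([2.0] * 10)

    def test_continuous_expression_splits_nearly_evenly(self):
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=100)
            labels = median_dichotomize(x)
            assert abs((labels == "HIGH").sum() - (labels == "LOW").sum()) <= 1


class TestKaplanMeier:
    def test_three_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert len(km.times) == 0  # no steps; S(t) = 1 throughout

    def test_negative_time_is_an_error(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])

    def test_mixed_fixture_matches_product_limit_table(self):
        times = [1, 2, 2, 3, 4, 5, 6, 7, 8, 9]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        km = km_estimate(times, [bool(e) for e in events])
        table = km_table(times, [bool(e) for e in events])
        np.testing.assert_allclose(km.survival, [s for *_ , s in table], atol=1e-9)
        # frozen expected values from the hand-tabulated product-limit table
        np.testing.assert_allclose(
            km.survival,
            [9 / 10, 4 / 5, 24 / 35, 96 / 175, 72 / 175, 36 / 175],
            atol=1e-12,
        )

    def test_without_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5.0, size=40)
        km = km_estimate(t, np.ones(40, dtype=bool))
        for ti, s in zip(km.times, km.survival):
            assert s == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(5.0, size=30)
        e = rng.random(30) < 0.7
        km = km_estimate(t, e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-9)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        labels = ["LOW"] * 3 + ["HIGH"] * 3
        chisq, p = logrank_test(labels, t, e)
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_hand_tabulation(self):
        labels = ["A", "A", "B", "B"]
        t = [1.0, 2.0, 10.0, 20.0]
        e = [True] * 4
        chisq, p = logrank_test(labels, t, e)
        O1, E1, V = logrank_oe(labels, t, e, group1="A")
        assert chisq == pytest.approx((O1 - E1) ** 2 / V, abs=1e-12)
        assert chisq == pytest.approx(49 / 17, abs=1e-12)  # frozen hand value
        assert p == pytest.approx(float(stats.chi2.sf(49 / 17, 1)), abs=1e-12)

    def test_label_swap_leaves_statistic_unchanged(self, rng):
        t = rng.exponential(3.0, size=30)
        e = rng.random(30) < 0.8
        labels = np.where(rng.random(30) < 0.5, "LOW", "HIGH")
        swapped = np.where(labels == "LOW", "HIGH", "LOW")
        assert logrank_test(labels, t, e) == pytest.approx(
            logrank_test(swapped, t, e)
        )

    def test_invariant_to_monotone_time_transform(self, rng):
        t = rng.exponential(3.0, size=30) + 0.1
        e = rng.random(30) < 0.8
        labels = np.where(rng.random(30) < 0.5, "LOW", "HIGH")
        assert logrank_test(labels, t, e) == pytest.approx(
            logrank_test(labels, np.log(t), e)
        )

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            logrank_test(["LOW"] * 4, [1.0, 2.0, 3.0, 4.0], [True] * 4)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(3.0, size=40)
        e = rng.random(40) < 0.75
        labels = np.where(rng.random(40) < 0.5, "LOW", "HIGH")
        chisq, p = logrank_test(labels, t, e)
        res = ll_logrank(
            t[labels == "LOW"], t[labels == "HIGH"],
            e[labels == "LOW"], e[labels == "HIGH"],
        )
        assert chisq == pytest.approx(res.test_statistic, abs=1e-9)
        assert p == pytest.approx(res.p_value, abs=1e-9)


class TestHazardRatio:
    def test_identical_groups_give_unity(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["LOW"] * 3 + ["HIGH"] * 3
        assert hazard_ratio(labels, t, [True] * 6) == pytest.approx(1.0)

    def test_low_group_with_earlier_events_exceeds_one(self):
        labels = ["LOW", "LOW", "HIGH", "HIGH"]
        t = [1.0, 2.0, 10.0, 20.0]
        hr = hazard_ratio(labels, t, [True] * 4)
        assert hr > 1
        assert hr == pytest.approx(
            mh_hazard_ratio(labels, t, [True] * 4, "LOW", "HIGH"), abs=1e-12
        )
        assert hr == pytest.approx(19 / 5, abs=1e-12)  # frozen hand value

    def test_label_swap_gives_reciprocal(self, rng):
        t = rng.exponential(3.0, size=30)
        e = np.ones(30, dtype=bool)
        labels = np.where(rng.random(30) < 0.5, "LOW", "HIGH")
        swapped = np.where(labels == "LOW", "HIGH", "LOW")
        assert hazard_ratio(labels, t, e) == pytest.approx(
            1.0 / hazard_ratio(swapped, t, e)
        )


class TestValidateCohort:
    def test_chemo_only_on_untreated_cohort_is_an_error(self, rng):
        cohort = cohort_from(
            rng.normal(size=10), rng.exponential(5, 10), [True] * 10, [False] * 10
        )
        with pytest.raises(ValueError):
            validate_cohort(cohort, subset_chemo_only=True)

    def test_median_is_recomputed_on_the_chemo_subset(self):
        # treated patients have systematically higher expression; the subset
        # median must split the 6 treated patients 3/3 regardless of the rest
        expr = [0.0, 0.1, 0.2, 0.3, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0]
        chemo = [False] * 4 + [True] * 6
        cohort = cohort_from(expr, np.arange(1.0, 11.0), [True] * 10, chemo)
        comp = validate_cohort(cohort, subset_chemo_only=True)
        assert comp.n_high == 3 and comp.n_low == 3

    def test_treated_benefit_is_detected_in_chemo_only_analysis(self):
        cohort, _ = generate_clinical_cohort(
            SyntheticClinicalConfig(n_patients=150, gamma=1.0, seed=11)
        )
        comp = validate_cohort(cohort, subset_chemo_only=True)
        assert comp.p <= 0.05
        assert comp.hr > 1  # low expression carries the higher hazard


class TestZScoreAndWelch:
    def test_three_point_zscore(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_zscore_output_standardized_and_affine_invariant(self, rng):
        x = rng.normal(3.0, 2.5, size=50)
        z = zscore(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(z, zscore(4.0 * x - 7.0), atol=1e-9)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError):
            zscore([1.0, 1.0, 1.0])

    def test_equal_groups_give_t_zero(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_fixture_matches_formula_oracle_and_scipy(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]
        t, df, p = welch_t(a, b)
        t_o, df_o, p_o = welch_formulas(a, b)
        assert t == pytest.approx(t_o, abs=1e-12)
        assert df == pytest.approx(df_o, abs=1e-12)
        assert df == pytest.approx(6.0, abs=1e-12)  # equal-variance case
        assert p == pytest.approx(p_o, abs=1e-12)
        sp = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(sp.statistic, abs=1e-9)
        assert p == pytest.approx(sp.pvalue, abs=1e-9)

    def test_welch_null_rejection_rate_is_calibrated(self):
        rej = 0
        n_sims = 1000
        master = np.random.default_rng(99)
        for _ in range(n_sims):
            a = master.normal(size=10)
            b = master.normal(size=10)
            _, _, p = welch_t(a, b)
            rej += p <= 0.05
        assert abs(rej / n_sims - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestResponders:
    def test_clear_separation_is_significant(self, rng):
        expr = np.r_[np.zeros(6), np.ones(6)] + rng.normal(0, 1e-3, 12)
        resp = ["NON_RESPONDER"] * 6 + ["RESPONDER"] * 6
        cohort = cohort_from(
            expr, np.ones(12), [True] * 12, [True] * 12, response=resp
        )
        out = compare_responders(cohort)
        assert out.p < 0.01
        assert out.mean_responder > out.mean_non_responder

    def test_small_group_is_an_error(self, rng):
        expr = rng.normal(size=5)
        resp = ["RESPONDER"] + ["NON_RESPONDER"] * 4
        cohort = cohort_from(expr, np.ones(5), [True] * 5, [True] * 5, response=resp)
        with pytest.raises(ValueError):
            compare_responders(cohort)


class TestCohortIO:
    def test_missing_column_error_names_the_column(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("patient_id\texpr\ttime\tevent\nP1\t1\t2\t1\n")
        with pytest.raises(ValueError, match="chemo"):
            read_cohort(p)

    def test_round_trip_with_response_labels(self, tmp_path):
        cohort, _ = generate_clinical_cohort(
            SyntheticClinicalConfig(n_patients=20, seed=5)
        )
        p = tmp_path / "c.tsv"
        write_cohort(cohort, p)
        back = read_cohort(p, cohort.cohort_id)
        np.testing.assert_allclose(back.data.expr, cohort.data.expr, rtol=1e-9)
        assert (back.data.event == cohort.data.event).all()
        assert (
            back.data.response.fillna("x") == cohort.data.response.fillna("x")
        ).all()
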