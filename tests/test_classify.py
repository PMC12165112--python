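"""Cutoff derivation, subtype and dual-marker calls, ROC/AUC, Mann-Whitney."""

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from evquant.classify import (
    ClassifyConfig,
    CutoffSet,
    assign_subtype,
    classify_cohort,
    combined_score,
    confusion_metrics,
    derive_cutoff_spec100,
    derive_cutoff_whisker,
    derive_cutoffs,
    dual_marker_call,
    mann_whitney,
    roc_auc,
    tukey_fences,
)
from evquant.simulate import default_cohort_config, simulate_cohort


def paper_style_cutoffs(**extra):
    """Cutoff set at the magnitudes the assay operates at."""
    cutoffs = {
        "ASCL1": 14295.0,
        "NEUROD1": 42819.0,
        "POU2F3": 185157.0,
        "DLL3_exo_mRNA": 160238.0,
        "DLL3_tEV_mProtein": 336847.0,
        **extra,
    }
    return CutoffSet(
        cutoffs=cutoffs, method={m: "whisker_max" for m in cutoffs}, control_group="HRS"
    )


class TestTukeyAndCutoffs:
    def test_hand_computed_fences_with_outlier(self):
        f = tukey_fences([1, 2, 3, 4, 100])
        assert (f.q1, f.q3, f.iqr) == (2.0, 4.0, 2.0)
        assert f.upper == 7.0
        assert set(f.inliers) == {1, 2, 3, 4}

    def test_constant_values_have_no_outliers(self):
        f = tukey_fences([5.0] * 6)
        assert f.iqr == 0.0
        assert len(f.inliers) == 6

    def test_symmetric_range_fences(self):
        # type-7 quartiles of 1..9 are exactly 3 and 7 -> fences -3 and 13
        f = tukey_fences(list(range(1, 10)))
        assert (f.q1, f.q3) == (3.0, 7.0)
        assert (f.lower, f.upper) == (-3.0, 13.0)
        assert len(f.inliers) == 9

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tukey_fences([1, 2, 3])

    def test_whisker_cutoff_is_max_inlier(self):
        assert derive_cutoff_whisker([1, 2, 3, 4, 100]) == 4.0
        assert derive_cutoff_whisker([3.0, 1.0, 2.0, 2.5]) == 3.0
        assert derive_cutoff_whisker([7.0] * 5) == 7.0

    def test_spec100_cutoff_is_control_max(self):
        assert derive_cutoff_spec100([5.0, 9.0, 7.0]) == 9.0
        assert derive_cutoff_spec100([4.2]) == 4.2
        with pytest.raises(ValueError):
            derive_cutoff_spec100([])

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_spec100_specificity_is_exactly_one_on_deriving_controls(self, controls):
        cutoff = derive_cutoff_spec100(controls)
        assert sum(v > cutoff for v in controls) == 0

    @given(st.lists(st.floats(0.1, 1e6), min_size=4, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_whisker_cutoff_never_exceeds_control_max(self, controls):
        assert derive_cutoff_whisker(controls) <= max(controls)


class TestSubtypeCalls:
    def test_ratio_rule_with_assay_scale_cutoffs(self):
        row = {
            "sample_id": "p1",
            "ASCL1": 28590.0,
            "NEUROD1": 10000.0,
            "POU2F3": 100000.0,
        }
        call = assign_subtype(row, paper_style_cutoffs())
        assert call.ratios["A"] == pytest.approx(2.000, abs=5e-4)
        assert call.ratios["N"] == pytest.approx(0.234, abs=5e-4)
        assert call.ratios["P"] == pytest.approx(0.540, abs=5e-4)
        assert call.positive == frozenset({"A"})
        assert call.primary == "A"

    def test_all_ratios_at_or_below_one_is_inflammatory_subtype(self):
        row = {"sample_id": "p2", "ASCL1": 14295.0, "NEUROD1": 100.0, "POU2F3": 100.0}
        call = assign_subtype(row, paper_style_cutoffs())
        assert call.positive == frozenset()
        assert call.primary == "I"  # boundary value is not positive (strict >)

    def test_tie_break_follows_fixed_order(self):
        cut = paper_style_cutoffs()
        row = {
            "sample_id": "p3",
            "ASCL1": 1.5 * cut["ASCL1"],
            "NEUROD1": 1.5 * cut["NEUROD1"],
            "POU2F3": 0.2 * cut["POU2F3"],
        }
        call = assign_subtype(row, cut)
        assert call.positive == frozenset({"A", "N"})
        assert call.primary == "A"

    def test_missing_marker_rejected(self):
        with pytest.raises(ValueError):
            assign_subtype({"sample_id": "p", "ASCL1": 1.0}, paper_style_cutoffs())


class TestDualCalls:
    def test_high_mrna_low_protein(self):
        row = {"sample_id": "d1", "DLL3_exo_mRNA": 200000.0, "DLL3_tEV_mProtein": 100000.0}
        call = dual_marker_call(row, paper_style_cutoffs())
        assert call.category == "HL"
        assert call.positive

    def test_double_low_is_negative(self):
        row = {"sample_id": "d2", "DLL3_exo_mRNA": 1000.0, "DLL3_tEV_mProtein": 1000.0}
        call = dual_marker_call(row, paper_style_cutoffs())
        assert call.category == "LL" and not call.positive

    def test_boundary_value_counts_as_low(self):
        row = {"sample_id": "d3", "DLL3_exo_mRNA": 160238.0, "DLL3_tEV_mProtein": 1.0}
        assert dual_marker_call(row, paper_style_cutoffs()).category == "LL"


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_interleaved_example(self):
        # pairs: 3 case-over-control wins of 4 -> AUC 0.75
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == 0.75

    def test_curve_monotone_and_matches_trapezoid(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=200), 1)  # heavy ties
        labels = rng.integers(0, 2, 200)
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.thresholds) < 0)
        assert np.all(np.diff(r.sensitivity) >= 0)  # as threshold drops
        fpr = np.r_[0.0, 1.0 - r.specificity, 1.0]
        tpr = np.r_[0.0, r.sensitivity, 1.0]
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = np.round(rng.normal(size=60), 1)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_auc_u_identity_with_ties(self):
        """AUC x n1 x n0 equals the Mann-Whitney U statistic, ties included."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            n1 = int(rng.integers(2, 15))
            n0 = int(rng.integers(2, 15))
            scores = np.round(rng.normal(size=n1 + n0), 0)  # many ties
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            r = roc_auc(scores, labels)
            mw = mann_whitney(scores[:n1], scores[n1:], mode="normal")
            assert r.auc * n1 * n0 == pytest.approx(mw.u, abs=1e-9)

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(3.0 * scores + 7.0, labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0.0
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.u == 4.5  # n^2 / 2
        assert res.p_value == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            ours = mann_whitney(x, y, mode="exact")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.u == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_mode_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = rng.normal(0.3, 1.0, size=35)
        ours = mann_whitney(x, y, mode="normal")
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert ours.u == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_null_rejection_rate_controlled(self):
        """Type-I error at alpha = 0.05 on same-distribution samples."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            if mann_whitney(x, y, mode="normal").p_value < 0.05:
                rejections += 1
        assert rejections / n_sims == pytest.approx(0.05, abs=0.03)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestConfusion:
    @pytest.mark.parametrize(
        "calls, labels, expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], (1.0, 1.0, 1.0)),
            ([0] * 20, [1] * 10 + [0] * 10, (0.0, 1.0, 0.5)),
            ([1] * 8 + [0] * 2 + [0] * 9 + [1], [1] * 10 + [0] * 10, (0.8, 0.9, 0.85)),
        ],
    )
    def test_two_by_two_ratios(self, calls, labels, expected):
        assert confusion_metrics(calls, labels) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


class TestCombinedScore:
    def test_single_marker_score_preserves_ranking(self):
        df = pd.DataFrame(
            {"sample_id": list("abcd"), "group": ["HRS", "HRS", "ES", "ES"],
             "ASCL1": [100.0, 900.0, 2000.0, 50000.0]}
        )
        cut = paper_style_cutoffs()
        scores = combined_score(df, ["ASCL1"], cut)
        labels = (df["group"] == "ES").astype(int).to_numpy()
        assert roc_auc(scores.to_numpy(), labels).auc == roc_auc(
            df["ASCL1"].to_numpy(), labels
        ).auc

    def test_positive_score_iff_any_marker_above_cutoff(self):
        cut = paper_style_cutoffs()
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "group": ["ES", "HRS"],
                "ASCL1": [20000.0, 1000.0],
                "POU2F3": [1000.0, 1000.0],
            }
        )
        scores = combined_score(df, ["ASCL1", "POU2F3"], cut)
        assert scores.iloc[0] > 0
        assert scores.iloc[1] < 0

    def test_informative_marker_dominates_combination(self):
        """Adding an uninformative marker does not destroy the AUC carried by
        the informative one."""
        rng = np.random.default_rng(7)
        n = 1000
        noise = 10 ** rng.normal(3.0, 0.3, 2 * n)
        signal = 10 ** np.r_[rng.normal(3.0, 0.3, n), rng.normal(3.8, 0.3, n)]
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(2 * n)],
                "group": ["HRS"] * n + ["ES"] * n,
                "M1": noise,
                "M2": signal,
            }
        )
        cut = CutoffSet(
            cutoffs={"M1": 10**3.7, "M2": 10**3.7},
            method={"M1": "whisker_max", "M2": "whisker_max"},
        )
        labels = (df["group"] == "ES").astype(int).to_numpy()
        auc_single = roc_auc(df["M2"].to_numpy(), labels).auc
        auc_comb = roc_auc(
            combined_score(df, ["M1", "M2"], cut).to_numpy(), labels
        ).auc
        assert auc_comb >= auc_single - 0.02

    def test_logistic_beats_chance_and_falls_back_on_separation(self, caplog):
        rng = np.random.default_rng(8)
        n = 200
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(2 * n)],
                "group": ["HRS"] * n + ["ES"] * n,
                "M1": 10 ** np.r_[rng.normal(3, 0.3, n), rng.normal(3.6, 0.3, n)],
            }
        )
        cut = CutoffSet(cutoffs={"M1": 10**3.5}, method={"M1": "spec100"})
        scores = combined_score(df, ["M1"], cut, method="logistic")
        labels = (df["group"] == "ES").astype(int).to_numpy()
        assert roc_auc(scores.to_numpy(), labels).auc > 0.8
        # perfectly separated classes -> documented fallback
        sep = pd.DataFrame(
            {
                "sample_id": list("abcdef"),
                "group": ["HRS"] * 3 + ["ES"] * 3,
                "M1": [10.0, 20.0, 30.0, 1e4, 2e4, 3e4],
            }
        )
        with caplog.at_level(logging.WARNING):
            s2 = combined_score(sep, ["M1"], cut, method="logistic")
        expected = np.log2(sep["M1"].to_numpy() / cut["M1"])
        np.testing.assert_allclose(s2.to_numpy(), expected)


class TestClassifyCohort:
    def test_cutoff_methods_and_determinism(self):
        df = simulate_cohort(default_cohort_config(seed=1))
        rep1 = classify_cohort(df)
        rep2 = classify_cohort(df)
        assert rep1.cutoffs.method["ASCL1"] == "whisker_max"
        assert rep1.cutoffs.method["DLL3_exo_mRNA"] == "spec100"
        assert rep1.cutoffs.cutoffs == rep2.cutoffs.cutoffs
        assert rep1.subtype_calls.equals(rep2.subtype_calls)
        controls = df[df["group"] == "HRS"]
        assert rep1.cutoffs["DLL3_exo_mRNA"] == controls["DLL3_exo_mRNA"].max()

    def test_every_sclc_sample_gets_exactly_one_primary_label(self):
        df = simulate_cohort(default_cohort_config(seed=2))
        rep = classify_cohort(df)
        n_sclc = int((df["group"] != "HRS").sum())
        assert len(rep.subtype_calls) == n_sclc
        assert rep.subtype_calls["primary"].isin(list("ANPI")).all()
        assert rep.subtype_prevalence["fraction"].sum() == pytest.approx(1.0)

    def test_dual_rule_sensitivity_one_when_all_cases_exceed_cutoff(self):
        df = simulate_cohort(default_cohort_config(seed=3))
        cases = df["group"] != "HRS"
        ceiling = df.loc[~cases, "DLL3_exo_mRNA"].max()
        df.loc[cases, "DLL3_exo_mRNA"] = ceiling * 10
        rep = classify_cohort(df)
        sens, spec, _ = rep.metrics["dual_DLL3|all_SCLC"]
        assert sens == 1.0
        assert spec == 1.0  # spec100 construction

    def test_missing_control_group_rejected(self):
        df = simulate_cohort(default_cohort_config(seed=4))
        with pytest.raises(ValueError):
            classify_cohort(df[df["group"] != "HRS"])

    def test_missing_marker_column_named_in_error(self):
        df = simulate_cohort(default_cohort_config(seed=5)).drop(columns=["POU2F3"])
        with pytest.raises(ValueError, match="POU2F3"):
            classify_cohort(df)

    def test_roc_keys_cover_markers_and_combinations(self):
        df = simulate_cohort(default_cohort_config(seed=6))
        rep = classify_cohort(df)
        for key in ("dual_DLL3|all_SCLC", "combined|LS", "combined|ES", "ASCL1|all_SCLC"):
            assert key in rep.roc
        assert rep.roc["combined|ES"].n_controls == 45
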