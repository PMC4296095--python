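"""Logistic fitting, univariate scans, percentile selection, stepwise models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, spearmanr

import gaitrisk as gr
from gaitrisk.errors import PerfectSeparationError

from .oracles import auc_concordance, logistic_grid_fit


class TestZTransform:
    def test_standardizes(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, record, flagged = gr.z_transform(df)
        assert z["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["a"].std(ddof=0) == pytest.approx(1.0)
        assert not flagged

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 2.0]})
        _, record, flagged = gr.z_transform(df)
        assert flagged == ["a"]
        assert "a" not in record

    def test_back_transform_roundtrip(self):
        from gaitrisk.models import back_transform

        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.standard_normal(20) * 3 + 5})
        z, record, _ = gr.z_transform(df)
        np.testing.assert_allclose(back_transform(z, record)["a"], df["a"])


class TestFitLogistic:
    def test_intercept_only_is_log_odds(self):
        y = np.r_[np.ones(70), np.zeros(132)]
        fit = gr.fit_logistic(np.empty((202, 0)), y)
        assert fit.params[0] == pytest.approx(math.log(70 / 132), abs=1e-8)

    def test_matches_grid_search_oracle(self):
        x = np.array([-1.2, -0.3, 0.1, 0.8, 1.5, 2.0])
        y = np.array([0, 0, 1, 0, 1, 1])
        fit = gr.fit_logistic(x[:, None], y)
        b0, b1 = logistic_grid_fit(x, y)
        assert fit.params[0] == pytest.approx(b0, abs=1e-4)
        assert fit.params[1] == pytest.approx(b1, abs=1e-4)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.standard_normal((150, 3))
        eta = 0.4 * X[:, 0] - 0.7 * X[:, 2] - 0.2
        y = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = gr.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-5)

    def test_perfect_separation_detected(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(PerfectSeparationError):
            gr.fit_logistic(x[:, None], y)

    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(2000)
        y = rng.integers(0, 2, 2000)
        fit = gr.fit_logistic(x[:, None], y)
        assert abs(fit.params[1]) < 3 * fit.bse[1]


class TestRocAuc:
    def test_perfect_separation(self):
        assert gr.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_independent_near_half(self):
        rng = np.random.default_rng(4)
        p = rng.random(4000)
        y = rng.integers(0, 2, 4000)
        assert gr.roc_auc(p, y) == pytest.approx(0.5, abs=0.05)

    def test_matches_concordance_oracle_with_ties(self):
        p = np.array([0.2, 0.5, 0.5, 0.7, 0.3, 0.7, 0.1, 0.5])
        y = np.array([0, 1, 0, 1, 0, 0, 0, 1])
        assert gr.roc_auc(p, y) == pytest.approx(auc_concordance(p, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40)
        y = np.r_[np.ones(15), np.zeros(25)].astype(int)
        rng.shuffle(y)
        a = gr.roc_auc(p, y)
        b = gr.roc_auc(np.exp(3 * p) + 1, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.random(60)
        y = rng.integers(0, 2, 60)
        pts = gr.roc_curve_points(p, y)
        assert pts["fpr"].is_monotonic_increasing
        assert pts["tpr"].is_monotonic_increasing


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups(self):
        # 10 groups of 10 where observed = expected exactly
        prs = np.r_[np.arange(1, 10) / 10, 0.5]
        prs.sort()
        p_hat = np.repeat(prs, 10)
        y = np.concatenate([
            np.r_[np.ones(round(pr * 10)), np.zeros(10 - round(pr * 10))]
            for pr in prs
        ])
        stat, p = gr.hosmer_lemeshow(p_hat, y, groups=10)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula_two_groups(self):
        p_hat = np.r_[np.full(10, 0.2), np.full(10, 0.7)]
        y = np.r_[np.ones(4), np.zeros(6), np.ones(5), np.zeros(5)]
        stat, _ = gr.hosmer_lemeshow(p_hat, y, groups=2)
        expected = (4 - 2.0) ** 2 / (2.0 * (1 - 0.2)) + (5 - 7.0) ** 2 / (
            7.0 * (1 - 0.7)
        )
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_rejection_rate_under_well_specified_model(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.standard_normal(250)
            prob = 1 / (1 + np.exp(-(0.8 * x - 0.4)))
            y = (rng.random(250) < prob).astype(float)
            try:
                fit = gr.fit_logistic(x[:, None], y)
            except PerfectSeparationError:
                continue
            _, p = gr.hosmer_lemeshow(fit.predict(x[:, None]), y)
            rejections += p < 0.05
        assert 0.01 <= rejections / n_rep <= 0.12


class TestUnivariateScan:
    def test_duplicated_predictor_identical_results(self):
        p = gr.FeatureCohortParams(n_participants=120, seed=2)
        df, _ = gr.synth_feature_cohort(p)
        df["gds_copy"] = df["gds"]
        scan = gr.univariate_scan(df)
        a = scan[scan["column"] == "gds"].iloc[0]
        b = scan[scan["column"] == "gds_copy"].iloc[0]
        assert a["B"] == pytest.approx(b["B"], abs=1e-10)
        assert a["p"] == pytest.approx(b["p"], abs=1e-10)

    def test_constant_column_flagged(self):
        p = gr.FeatureCohortParams(n_participants=60, seed=3)
        df, _ = gr.synth_feature_cohort(p)
        df["constant"] = 1.0
        scan = gr.univariate_scan(df)
        row = scan[scan["column"] == "constant"].iloc[0]
        assert row["note"] == "flagged"
        assert np.isnan(row["B"])

    def test_null_pvalues_uniform(self):
        # outcome independent of a pure-noise predictor: p-values ~ U(0,1)
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(400):
            x = rng.standard_normal(150)
            y = (rng.random(150) < 0.35).astype(float)
            if y.sum() in (0, 150):
                continue
            fit = gr.fit_logistic(x[:, None], y)
            pvals.append(fit.pvalues[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_scan_matches_single_fits(self):
        p = gr.FeatureCohortParams(
            n_participants=150, seed=5,
            outcome_coefficients={"gait_speed__p50": -0.6},
        )
        df, _ = gr.synth_feature_cohort(p)
        scan = gr.univariate_scan(df)
        col = "gait_speed__p50"
        x = df[col].to_numpy()
        z = (x - x.mean()) / x.std(ddof=0)
        ref = gr.fit_logistic(z[:, None], df["faller"].to_numpy())
        row = scan[scan["column"] == col].iloc[0]
        assert row["B"] == pytest.approx(ref.params[1], abs=1e-6)
        assert row["p"] == pytest.approx(ref.pvalues[1], abs=1e-6)


class TestSelectStrongerPercentile:
    @staticmethod
    def _scan(p10, p50, p90):
        return pd.DataFrame(
            {
                "parameter": ["f"] * 3,
                "percentile": [10, 50, 90],
                "column": ["f__p10", "f__p50", "f__p90"],
                "B": [0.3, 0.3, 0.3],
                "p": [p10, p50, p90],
            }
        )

    def test_low_extreme_chosen_when_strongest(self):
        choice = gr.select_stronger_percentile(self._scan(0.03, 0.07, 0.61))
        assert choice["f"] == 10

    def test_high_extreme_chosen_when_strongest(self):
        choice = gr.select_stronger_percentile(self._scan(0.83, 0.009, 0.003))
        assert choice["f"] == 90

    def test_median_retained_when_nothing_significant(self):
        choice = gr.select_stronger_percentile(self._scan(0.20, 0.08, 0.30))
        assert choice["f"] == 50

    def test_missing_percentile_defaults_to_median(self):
        scan = self._scan(0.01, 0.02, 0.03).iloc[:2]
        choice = gr.select_stronger_percentile(scan)
        assert choice["f"] == 50


class TestStepwise:
    def test_single_informative_candidate_selected(self):
        p = gr.FeatureCohortParams(
            n_participants=500, seed=8,
            outcome_coefficients={"sample_entropy_vt__p50": 0.8},
        )
        df, _ = gr.synth_feature_cohort(p)
        cols = gr.models.model_candidate_columns(df, "model2")
        model = gr.stepwise_forward(df[cols], df["faller"].to_numpy())
        assert "sample_entropy_vt__p50" in model.parameters

    def test_duplicate_candidate_screened_out(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(int)
        cands = pd.DataFrame({"a_feature": x, "b_copy": x.copy()})
        model = gr.stepwise_forward(cands, y)
        assert len(model.parameters) == 1

    def test_rho_screen_holds_post_hoc(self):
        p = gr.FeatureCohortParams(
            n_participants=300, seed=12,
            outcome_coefficients={"sample_entropy_vt__p50": 0.7,
                                  "gait_speed__p50": -0.5},
        )
        df, _ = gr.synth_feature_cohort(p)
        cols = gr.models.model_candidate_columns(df, "model2")
        model = gr.stepwise_forward(df[cols], df["faller"].to_numpy())
        assert len(model.parameters) >= 1
        for i, a in enumerate(model.parameters):
            for b in model.parameters[i + 1:]:
                rho = spearmanr(df[a], df[b]).statistic
                assert abs(rho) <= 0.7 + 1e-12

    def test_no_qualifying_candidate_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        y = (rng.random(200) < 0.35).astype(int)
        cands = pd.DataFrame({"noise": np.full(200, 1.0)})  # degenerate
        model = gr.stepwise_forward(cands, y)
        assert model.parameters == []
        assert any("intercept-only" in n for n in model.notes)
        assert model.auc == pytest.approx(0.5)

    def test_alpha_one_selects_until_exhaustion(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((150, 4)),
                         columns=list("abcd"))
        y = (rng.random(150) < 0.4).astype(int)
        model = gr.stepwise_forward(X, y, alpha=1.0)
        assert len(model.parameters) == 4


class TestBuildModels:
    def test_three_models_deterministic(self):
        p = gr.FeatureCohortParams(
            n_participants=202, seed=3,
            outcome_coefficients={"fall_history": 0.5, "gds": 0.35,
                                  "sample_entropy_vt__p10": 0.65},
        )
        df, _ = gr.synth_feature_cohort(p)
        m1 = gr.build_models(df)
        m2 = gr.build_models(df)
        for k in (1, 2, 3):
            assert m1[k].parameters == m2[k].parameters
            assert m1[k].auc == m2[k].auc

    def test_model1_candidates_are_questionnaire_only(self):
        p = gr.FeatureCohortParams(
            n_participants=202, seed=3,
            outcome_coefficients={"fall_history": 0.6, "gds": 0.4},
        )
        df, _ = gr.synth_feature_cohort(p)
        models = gr.build_models(df)
        assert set(models[1].parameters) <= {"fall_history", "gds"}

    def test_nested_models_do_not_lose_auc_in_null(self):
        # sensor block independent of outcome: model 2/3 stay near model 1
        deltas = []
        for seed in range(8):
            p = gr.FeatureCohortParams(
                n_participants=500, seed=seed,
                questionnaire_quality_loading=0.0,
                outcome_coefficients={"fall_history": 0.6, "gds": 0.4},
            )
            df, _ = gr.synth_feature_cohort(p)
            models = gr.build_models(df)
            deltas.append(models[2].auc - models[1].auc)
        assert np.mean(deltas) < 0.05
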