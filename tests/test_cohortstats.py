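"""Cohort statistics: exclusions, generator, stepwise AIC, ROC, agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ssbmd import cohortstats as cs


class TestExclusions:
    def test_reference_roster_counts(self):
        # 261 enrolled, 4 excluded -> 257 retained; 492 reference forearms;
        # 490 analysis wrists; 1.53% participants / 6.13% wrists excluded.
        ledger = cs.apply_exclusions(cs.reference_roster())
        assert ledger.retained_participants == 257
        assert ledger.dxa_forearms == 492
        assert ledger.dr_wrists == 490
        assert round(ledger.pct_participants_excluded, 2) == 1.53
        assert round(ledger.pct_wrists_excluded, 2) == 6.13

    def test_no_exclusions_identity(self):
        roster = cs.reference_roster()
        roster["exclusion_reason"] = None
        roster[["dxa_left", "dxa_right", "dr_left", "dr_right"]] = True
        ledger = cs.apply_exclusions(roster)
        assert ledger.retained_participants == ledger.enrolled
        assert ledger.pct_participants_excluded == 0.0
        assert ledger.pct_wrists_excluded == 0.0

    def test_counting_oracle(self):
        # hand-count loop over the roster rows
        roster = cs.reference_roster()
        ledger = cs.apply_exclusions(roster)
        retained = forearms = wrists = 0
        for _, row in roster.iterrows():
            if row["exclusion_reason"] is not None:
                continue
            retained += 1
            for arm in ("left", "right"):
                if row[f"dxa_{arm}"]:
                    forearms += 1
                    if row[f"dr_{arm}"]:
                        wrists += 1
        assert (retained, forearms, wrists) == (
            ledger.retained_participants, ledger.dxa_forearms, ledger.dr_wrists
        )
        assert ledger.pct_wrists_excluded == pytest.approx(
            100.0 * (2 * len(roster) - wrists) / (2 * len(roster))
        )

    def test_conservation(self):
        ledger = cs.apply_exclusions(cs.reference_roster())
        assert ledger.retained_participants + sum(
            ledger.excluded_by_reason.values()
        ) == ledger.enrolled

    def test_missing_flags_rejected(self):
        roster = cs.reference_roster()
        roster["dxa_left"] = roster["dxa_left"].astype(object); roster.loc[5, "dxa_left"] = np.nan
        with pytest.raises(ValueError):
            cs.apply_exclusions(roster)


class TestGenerateCohort:
    def test_empty_cohort(self):
        df = cs.generate_cohort(0, seed=1)
        assert len(df) == 0

    def test_age_mean_on_target(self):
        # Sample mean age within 2 standard errors of the 70.92 y target.
        df = cs.generate_cohort(257, seed=1)
        ages = df.groupby("participant_id")["age"].first()
        assert abs(ages.mean() - 70.92) < 2 * 9.03 / np.sqrt(257)

    def test_device_moments_near_targets(self):
        df = cs.generate_cohort(600, seed=2)
        assert df["dev_bone_ud"].mean() == pytest.approx(1.03, abs=0.05)
        assert df["dev_thickness_ud"].mean() == pytest.approx(4.59, abs=0.12)
        assert df["dev_alloy_ud"].mean() == pytest.approx(0.78, abs=0.03)
        assert df["ref_abmd_ud"].std() == pytest.approx(0.09, abs=0.02)

    def test_variance_ratio_r2_oracle(self):
        # With latent correlation r between device bone thickness and the
        # reference, the regression R^2 must match r^2 = 1 - (resid/sd)^2.
        params = cs.CohortParams()
        df = cs.generate_cohort(4000, seed=3, params=params)
        r_target = params.device_corr("UD")
        r_obs = np.corrcoef(df["dev_bone_ud"], df["ref_abmd_ud"])[0, 1]
        assert r_obs**2 == pytest.approx(r_target**2, abs=0.02)

    def test_infeasible_residual_rejected(self):
        params = cs.CohortParams(residual_sd=0.10)  # exceeds the UD aBMD SD
        with pytest.raises(ValueError):
            cs.generate_cohort(10, seed=0, params=params)

    def test_deterministic(self):
        a = cs.generate_cohort(50, seed=9)
        b = cs.generate_cohort(50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestStepwise:
    @staticmethod
    def _structured(seed=1, n=400):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "x3": rng.normal(size=n),
        })
        df["y"] = 1.0 + 0.8 * df.x1 + 0.5 * df.x2**2 + rng.normal(0, 0.5, n)
        return df

    def test_informative_predictor_selected(self):
        rng = np.random.default_rng(0)
        n = 500
        df = pd.DataFrame({
            "signal": rng.normal(size=n),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        df["y"] = 2.0 + 1.5 * df["signal"] + rng.normal(0, 0.3, n)
        fit = cs.stepwise_aic_fit(df, "y", ["signal", "noise1", "noise2"])
        assert "signal" in fit.terms

    def test_matches_exhaustive_subset_minimum(self):
        # Greedy forward-backward search attains the global AIC minimum of
        # all 2^6 subsets on structured fixed-seed data.
        df = self._structured(seed=1)
        fit = cs.stepwise_aic_fit(df, "y", ["x1", "x2", "x3"])
        design = cs._quadratic_design(df, ["x1", "x2", "x3"])
        y = df["y"].to_numpy()
        best = np.inf
        for k in range(len(design.columns) + 1):
            for subset in itertools.combinations(design.columns, k):
                x = sm.add_constant(design[list(subset)], has_constant="add")
                best = min(best, sm.OLS(y, x).fit().aic)
        assert fit.aic == pytest.approx(best, abs=1e-6)

    def test_never_worse_than_empty_or_full(self):
        df = self._structured(seed=4)
        fit = cs.stepwise_aic_fit(df, "y", ["x1", "x2", "x3"])
        design = cs._quadratic_design(df, ["x1", "x2", "x3"])
        y = df["y"].to_numpy()
        full = sm.OLS(y, sm.add_constant(design, has_constant="add")).fit().aic
        empty = sm.OLS(y, np.ones((len(y), 1))).fit().aic
        assert fit.aic <= full + 1e-9
        assert fit.aic <= empty + 1e-9

    def test_perfect_linear_response(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.normal(size=100),
                           "x2": rng.normal(size=100),
                           "x3": rng.normal(size=100)})
        df["y"] = 3.0 - 2.0 * df.x1
        fit = cs.stepwise_aic_fit(df, "y", ["x1", "x2", "x3"])
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=100)})
        df["x2"] = df["x1"] * 2.0
        df["y"] = df["x1"] + rng.normal(size=100)
        with pytest.raises(cs.FittingError):
            cs.stepwise_aic_fit(df, "y", ["x1", "x2"], include_quadratic=False)


class TestBootstrap:
    def test_degenerate_constant_sample(self):
        lo, hi = cs.bootstrap_ci(np.mean, np.full(20, 3.7), b=200, seed=0)
        assert lo == hi == pytest.approx(3.7)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(100):
            s = rng.normal(size=30)
            lo, hi = cs.bootstrap_ci(np.mean, s, b=300, level=0.99, seed=7)
            assert lo <= s.mean() <= hi

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.bootstrap_ci(np.mean, np.array([1.0]), b=200)
        with pytest.raises(ValueError):
            cs.bootstrap_ci(np.mean, np.zeros(10), b=50)


class TestAuc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5, bool), np.ones(5, bool)]
        assert cs.auc_mann_whitney(scores, labels) == 1.0

    def test_pair_counting_oracle_small_sample(self):
        scores = np.array([0.2, 0.8, 0.5, 0.4, 0.9, 0.5])
        labels = np.array([False, True, True, False, True, False])
        pos = scores[labels]
        neg = scores[~labels]
        concordant = sum(
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p in pos for n in neg
        )
        oracle = concordant / (len(pos) * len(neg))
        assert cs.auc_mann_whitney(scores, labels) == pytest.approx(oracle, abs=0)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        labels = rng.random(10_000) < 0.3
        scores = rng.normal(size=10_000)
        assert cs.auc_mann_whitney(scores, labels) == pytest.approx(0.5, abs=0.02)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, bool), np.zeros(25, bool)]
        base = cs.auc_mann_whitney(scores, labels)
        assert cs.auc_mann_whitney(np.exp(scores), labels) == pytest.approx(base)
        assert cs.auc_mann_whitney(3 * scores - 7, labels) == pytest.approx(base)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.auc_mann_whitney(np.arange(4.0), np.ones(4, bool))


class TestRiskModel:
    def test_delong_ci_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(5)

        def make(n):
            labels = rng.random(n) < 0.4
            scores = labels * 1.0 + rng.normal(size=n)
            return scores, labels

        widths = []
        for n in (200, 2000):
            scores, labels = make(n)
            auc, (lo, hi) = cs.delong_ci(scores, labels, level=0.99)
            assert lo <= auc <= hi
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_fit_risk_model_outputs(self):
        rng = np.random.default_rng(6)
        t = rng.normal(-1.0, 1.5, 600)
        outcome = t + rng.normal(0, 0.8, 600) < -2.5
        model = cs.fit_risk_model(t, outcome, level=0.99)
        assert 0.5 < model.auc <= 1.0
        assert model.ci[0] <= model.auc <= model.ci[1]
        # ROC curve monotone non-decreasing
        assert np.all(np.diff(model.fpr) >= 0)
        assert np.all(np.diff(model.tpr) >= 0)
        # lower predicted T-score -> higher risk
        assert model.coefficients[1] < 0

    def test_single_class_outcome_rejected(self):
        with pytest.raises(cs.FittingError):
            cs.fit_risk_model(np.arange(10.0), np.zeros(10, bool))


class TestSensSpec:
    def test_all_positive_classifier(self):
        out = cs.sensitivity_specificity(np.ones(10, bool),
                                         np.r_[np.ones(4, bool), np.zeros(6, bool)])
        assert out.sensitivity == 1.0
        assert out.specificity == 0.0

    def test_direct_count_oracle(self):
        # TP=3 FN=2 TN=5 FP=1 -> sens 0.6, spec 5/6
        outcome = np.r_[np.ones(5, bool), np.zeros(6, bool)]
        predicted = np.r_[np.ones(3, bool), np.zeros(2, bool),
                          np.zeros(5, bool), np.ones(1, bool)]
        out = cs.sensitivity_specificity(predicted, outcome)
        assert out.sensitivity == pytest.approx(0.6)
        assert out.specificity == pytest.approx(5 / 6)

    def test_cis_contain_point_estimates(self, rng):
        for _ in range(20):
            outcome = rng.random(60) < 0.4
            predicted = rng.random(60) < 0.5
            if outcome.all() or not outcome.any():
                continue
            out = cs.sensitivity_specificity(predicted, outcome, level=0.99)
            assert out.sensitivity_ci[0] <= out.sensitivity <= out.sensitivity_ci[1]
            assert out.specificity_ci[0] <= out.specificity <= out.specificity_ci[1]


class TestBlandAltman:
    def test_identity(self):
        a = np.linspace(-3, 1, 20)
        out = cs.bland_altman(a, a)
        assert out.bias == 0.0 and out.lower == 0.0 and out.upper == 0.0

    def test_constant_offset(self):
        a = np.linspace(-3, 1, 20)
        out = cs.bland_altman(a + 0.5, a)
        assert out.bias == pytest.approx(0.5)

    def test_direct_computation_oracle(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        out = cs.bland_altman(a, b)
        diff = a - b
        assert out.bias == pytest.approx(diff.mean())
        assert out.sd == pytest.approx(diff.std(ddof=1))
        assert out.lower == pytest.approx(diff.mean() - 1.96 * diff.std(ddof=1))
        assert out.upper == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cs.bland_altman(np.zeros(3), np.zeros(4))


class TestCohortSummary:
    def test_identical_groups_null_case(self, rng):
        x = rng.normal(size=40)
        df = pd.DataFrame({"v": np.r_[x, x]})
        group = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        out = cs.cohort_summary(df, group, continuous=["v"])
        row = out.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-9)
        assert row["auc"] == pytest.approx(0.5, abs=1e-9)

    def test_rank_statistic_matches_enumeration(self):
        # 3-vs-3: the rank-sum statistic equals the pairwise count oracle.
        from scipy import stats

        df = pd.DataFrame({"v": [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]})
        group = np.array([True, True, True, False, False, False])
        out = cs.cohort_summary(df, group, continuous=["v"])
        g1 = df["v"][group].to_numpy()
        g0 = df["v"][~group].to_numpy()
        u_oracle = sum(1.0 if a > b else (0.5 if a == b else 0.0)
                       for a in g1 for b in g0)
        assert out.iloc[0]["w"] == pytest.approx(
            stats.mannwhitneyu(g1, g0, alternative="two-sided").statistic
        )
        assert out.iloc[0]["w"] == pytest.approx(u_oracle)

    def test_schema_mirrors_clinical_table(self):
        df = cs.generate_cohort(120, seed=8)
        part = df.groupby("participant_id").first().reset_index()
        group = (df.groupby("participant_id")["ref_t_ud"].min() <= -2.5).to_numpy()
        out = cs.cohort_summary(
            part, group,
            continuous=["age", "height", "weight"],
            categorical=["previous_fracture"],
        )
        for col in ("mean_all", "sd_all", "mean_group", "mean_rest", "t", "w", "auc"):
            assert col in out.columns
        cat = out[out["kind"] == "categorical"].iloc[0]
        assert np.isfinite(cat["p_value"]) or np.isnan(cat["p_value"])

    def test_single_group_rejected(self):
        df = pd.DataFrame({"v": np.arange(5.0)})
        with pytest.raises(ValueError):
            cs.cohort_summary(df, np.ones(5, bool), continuous=["v"])


def test_run_validation_report_shape():
    report = cs.run_validation(n=257, seed=1, bootstrap_b=200)
    for region in ("UD", "DT"):
        stats_ = report["regions"][region]
        assert 0.0 < stats_["adj_r2"] <= 1.0
        assert stats_["risk_auc_ci"][0] <= stats_["risk_auc"] <= stats_["risk_auc_ci"][1]
        assert stats_["residual_sd"] == pytest.approx(0.042, abs=0.01)
    assert "fracture_screen" in report and "demographics" in report
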