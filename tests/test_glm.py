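"""GLM fitting, AIC selection, normality diagnostics and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trunksleep as ts
from trunksleep import glm
from tests.conftest import null_cohort_config, truth_cohort_table


def rng(seed=0):
    return np.random.default_rng(seed)


class TestFitGLM:
    def test_normal_identity_intercept_is_mean(self):
        y = rng(1).gamma(2.0, 3.0, 300)
        fit = glm.fit_glm(pd.DataFrame({"y": y}), "y", "1", "normal", "identity")
        assert fit.params["Intercept"] == pytest.approx(y.mean(), rel=1e-9)

    def test_gamma_log_intercept_is_log_mean(self):
        y = rng(2).gamma(2.0, 3.0, 300)
        fit = glm.fit_glm(pd.DataFrame({"y": y}), "y", "1", "gamma", "log")
        assert fit.params["Intercept"] == pytest.approx(np.log(y.mean()), rel=1e-6)

    def test_normal_identity_aic_matches_least_squares_closed_form(self):
        """AIC oracle: OLS residuals via numpy lstsq, Gaussian ML variance,
        k = coefficients + 1 dispersion."""
        r = rng(3)
        x = r.normal(size=200)
        y = 2.0 + 1.5 * x + r.normal(0, 0.7, 200)
        fit = glm.fit_glm(pd.DataFrame({"y": y, "x": x}), "y", "x",
                          "normal", "identity")
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        n = y.size
        sigma2 = rss / n
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        k = 2 + 1
        assert fit.aic == pytest.approx(2 * k - 2 * ll, rel=1e-9)

    def test_gamma_rejects_nonpositive_response(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 0.0, 3.0]})
        with pytest.raises(ts.InputError, match="offending rows"):
            glm.fit_glm(df, "y", "1", "gamma", "log")

    def test_gamma_log_parameter_recovery(self):
        """Known-coefficient gamma/log simulation: estimates within 3 SE."""
        r = rng(4)
        n = 2000
        x1, x2 = r.normal(size=n), r.integers(0, 2, n).astype(float)
        eta = 1.2 + 0.4 * x1 - 0.3 * x2
        y = r.gamma(3.0, np.exp(eta) / 3.0)
        fit = glm.fit_glm(pd.DataFrame({"y": y, "x1": x1, "x2": x2}),
                          "y", "x1 + x2", "gamma", "log")
        for name, true in [("Intercept", 1.2), ("x1", 0.4), ("x2", -0.3)]:
            assert abs(fit.params[name] - true) < 3.0 * fit.bse[name]

    def test_loglik_never_decreases_with_added_term(self):
        r = rng(5)
        n = 400
        df = pd.DataFrame({
            "y": r.gamma(2.0, 2.0, n),
            "a": r.integers(0, 3, n).astype(str),
            "b": r.integers(0, 2, n).astype(str),
        })
        for dist, link in [("normal", "identity"), ("gamma", "log")]:
            red = glm.fit_glm(df, "y", "C(a) + C(b)", dist, link)
            full = glm.fit_glm(df, "y", "C(a) + C(b) + C(a):C(b)", dist, link)
            assert full.loglik >= red.loglik - 1e-6


class TestSelectModel:
    def test_lower_aic_candidate_wins(self):
        y = rng(6).gamma(3.0, 2.0, 500)
        best, table = glm.select_model(
            pd.DataFrame({"y": y}), "y", "1",
            candidates=[("normal", "identity"), ("gamma", "log")])
        converged = table[table.converged]
        assert best.aic == converged.aic.min()

    def test_gamma_log_data_selects_gamma(self):
        r = rng(7)
        n = 1500
        x = r.normal(size=n)
        y = r.gamma(3.0, np.exp(1.0 + 0.3 * x) / 3.0)
        best, _ = glm.select_model(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert best.distribution == "gamma"

    def test_normal_identity_data_keeps_truth_near_minimum(self):
        r = rng(8)
        n = 1500
        x = r.normal(size=n)
        y = 10.0 + 2.0 * x + r.normal(0, 1.0, n)
        best, table = glm.select_model(pd.DataFrame({"y": y, "x": x}), "y", "x")
        row = table[(table.distribution == "normal") & (table.link == "identity")]
        assert float(row.aic.iloc[0]) <= table[table.converged].aic.min() + 2.0

    def test_failed_candidates_reported_not_raised(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 0.5, 3.0] * 10})
        df.loc[0, "y"] = 0.0  # kills the gamma candidates
        best, table = glm.select_model(df, "y", "1")
        assert best.distribution == "normal"
        gamma_rows = table[table.distribution == "gamma"]
        assert (~gamma_rows.converged).all()
        assert gamma_rows.message.str.contains("positive").all()


class TestNormalityChecks:
    def test_normal_sample_not_rejected(self):
        res = glm.normality_checks(rng(9).normal(0, 1, 1000), n_mc=99, seed=1)
        for t in res["tests"].values():
            assert t["pvalue"] > 0.01

    def test_gamma_sample_rejected(self):
        """Power check: clearly skewed data rejected by all three EDF tests
        in nearly every replicate."""
        reject_all = 0
        reps = 10
        for i in range(reps):
            res = glm.normality_checks(rng(100 + i).gamma(2.0, 1.0, 500),
                                       n_mc=199, seed=i)
            if all(t["reject_normal"] for t in res["tests"].values()):
                reject_all += 1
        assert reject_all >= reps - 1

    def test_constant_sample_rejected_as_degenerate(self):
        with pytest.raises(ts.InputError):
            glm.normality_checks(np.full(100, 3.0))

    def test_too_small_sample(self):
        with pytest.raises(ts.InputError):
            glm.normality_checks(np.arange(5.0))

    def test_qq_data_shape(self):
        res = glm.normality_checks(rng(10).normal(size=64), n_mc=29, seed=0)
        assert list(res["qq"].columns) == ["theoretical", "sample"]
        assert len(res["qq"]) == 64


class TestBonferroniAndTests:
    @given(st.integers(min_value=0, max_value=5000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bonferroni_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(1, 12))
        p = r.random(m)
        adj = glm.bonferroni_adjust(p, m)
        expected = [min(1.0, m * v) for v in p]
        np.testing.assert_allclose(adj, expected)

    def test_f_test_agrees_with_anova_for_normal_identity(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        r = rng(11)
        df = pd.DataFrame({"y": r.normal(10, 2, 200),
                           "g": r.integers(0, 4, 200).astype(str)})
        full = glm.fit_glm(df, "y", "C(g)", "normal", "identity")
        red = glm.fit_glm(df, "y", "1", "normal", "identity")
        p = glm.f_test_nested(full, red)
        ols = smf.ols("y ~ C(g)", data=df).fit()
        expected = float(anova_lm(ols)["PR(>F)"].iloc[0])
        assert p == pytest.approx(expected, rel=1e-6)


class TestSummaries:
    def test_hand_built_table_means_and_sems(self):
        table = glm.build_cohort_table(pd.DataFrame({
            "age": [25, 27, 34, 36],
            "gender": ["male", "male", "female", "female"],
            "month": [1, 1, 2, 2],
            "tst_min": [400.0, 420.0, 380.0, 390.0],
        }))
        out = glm.summarize_by_group(table, parameters=["tst_min"])
        g20 = out[out.age_group == "20s"].iloc[0]
        assert g20["mean"] == pytest.approx(410.0)
        assert g20["sem"] == pytest.approx(np.std([400, 420], ddof=1) / np.sqrt(2))
        assert g20["n"] == 2

    def test_single_subject_cell_sem_undefined(self):
        table = glm.build_cohort_table(pd.DataFrame({
            "age": [25], "gender": ["male"], "month": [1], "tst_min": [400.0]}))
        out = glm.summarize_by_group(table, parameters=["tst_min"])
        assert np.isnan(out.iloc[0]["sem"]) and not out.iloc[0]["sem_defined"]

    def test_clock_mean_handles_midnight_wrap(self):
        # 23:50 and 00:10 average to midnight, not noon
        assert glm.clock_mean(np.array([1430.0, 10.0])) == pytest.approx(0.0)

    def test_u_shaped_tib_nadir_recovered(self, effect_cohort_table):
        out = glm.summarize_by_group(effect_cohort_table, parameters=["tib_min"])
        nadir = out.loc[out["mean"].idxmin(), "age_group"]
        assert nadir == "40s"


class TestAnalyzeParameter:
    def test_contrasts_reference_fixed_to_20s(self, effect_cohort_table):
        report = glm.analyze_parameter(effect_cohort_table, "waso")
        age_rows = report.contrasts[report.contrasts.group != "gender"]
        assert set(age_rows.group) <= {"10s", "30s", "40s", "50s", "60s", "70s", "80s"}
        assert (age_rows.reference == "20s").all()

    def test_planted_interaction_takes_stratified_path(self):
        """A female-only age decline must trigger stratification."""
        r = rng(12)
        n = 4000
        age = r.integers(10, 90, n)
        female = r.random(n) < 0.5
        y = 90.0 - np.where(female, 0.15 * np.maximum(age - 20, 0), 0.0) \
            + r.normal(0, 5.0, n)
        table = glm.build_cohort_table(pd.DataFrame({
            "age": age,
            "gender": np.where(female, "female", "male"),
            "month": r.integers(1, 13, n),
            "se_pct": y,
        }))
        report = glm.analyze_parameter(table, "se")
        assert report.interaction_significant
        assert report.path == "stratified"
        strata = set(report.contrasts.stratum)
        assert {"female", "male"} <= strata

    def test_null_cohort_reports_no_age_effect(self):
        table = truth_cohort_table(null_cohort_config(400, seed=555))
        report = glm.analyze_parameter(table, "tst")
        if report.path == "main_effects":
            assert report.main_effects["age_group"] > 0.01
        assert not report.contrasts.empty or report.path == "stratified"

    def test_missing_parameter_rejected(self, effect_cohort_table):
        with pytest.raises(ts.InputError):
            glm.analyze_parameter(effect_cohort_table, "nonexistent")


class TestEffectRecovery:
    def test_linear_effects_recovered_within_three_se(self, effect_cohort_table):
        cfg = ts.CohortConfig()
        est = glm.estimate_linear_effects(effect_cohort_table)
        ibt = est["ibt_slope_min_per_decade"]
        assert abs(ibt["estimate"] - (-cfg.ibt_advance_per_decade)) < 3 * ibt["se"]
        waso = est["waso_slope_min_per_decade"]
        assert abs(waso["estimate"] - cfg.waso_slope_per_decade) < 3 * waso["se"]
        gap = est["gender_tst_gap_min"]
        assert abs(gap["estimate"] - cfg.gender_tst_gap) < 3 * gap["se"]
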