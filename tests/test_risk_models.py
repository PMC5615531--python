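"""Crude ORs, group comparisons, correlations, and the IRLS logistic engine."""

import numpy as np
import pandas as pd
import pytest

from geovuln.risk_models import (MODEL_TERMS, LogisticModelSpec,
                                 LogisticRegressionIRLS, ORResult,
                                 TwoByTwoTable, adjusted_ors,
                                 complete_case_filter, correlation_matrix,
                                 crude_or, fit_logistic_irls, group_compare,
                                 reconstruct_table)


def _expand(table: TwoByTwoTable) -> pd.DataFrame:
    """Individual-level rows from a 2x2 table (exposure x case)."""
    rows = ([(1, 1)] * table.a + [(0, 1)] * table.b
            + [(1, 0)] * table.c + [(0, 0)] * table.d)
    return pd.DataFrame(rows, columns=["exposed", "case"])


class TestReconstructTable:
    @pytest.mark.parametrize("args, expected", [
        ((364, 19.8, 3566, 12.9), (72, 292, 460, 3106)),
        ((364, 39.6, 3566, 28.1), (144, 220, 1002, 2564)),
        ((100, 0.0, 100, 0.0), (0, 100, 0, 100)),
    ])
    def test_counts(self, args, expected):
        t = reconstruct_table(*args)
        assert (t.a, t.b, t.c, t.d) == expected

    def test_margins_preserved(self):
        t = reconstruct_table(364, 45.6, 3566, 50.5)
        assert t.n_cases == 364 and t.n_controls == 3566

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_table(-1, 10.0, 100, 10.0)


class TestCrudeOR:
    def test_living_alone_published_values(self):
        res = crude_or(TwoByTwoTable(a=72, b=292, c=460, d=3106))
        assert round(res.or_point, 2) == 1.66
        assert round(res.ci_low, 2) == 1.26
        assert round(res.ci_high, 2) == 2.19
        assert res.significant

    def test_balanced_table_is_null_and_log_symmetric(self):
        res = crude_or(TwoByTwoTable(a=10, b=10, c=10, d=10))
        assert res.or_point == pytest.approx(1.0)
        assert np.log(res.ci_high) == pytest.approx(-np.log(res.ci_low))
        assert not res.significant

    def test_against_independent_log_or_implementation(self):
        # oracle: statsmodels Table2x2 (normal-approximation CI)
        import statsmodels.api as sm
        t = TwoByTwoTable(a=5, b=5, c=2, d=8)
        res = crude_or(t)
        oracle = sm.stats.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        assert res.or_point == pytest.approx(oracle.oddsratio, rel=1e-12)
        lo, hi = oracle.oddsratio_confint(0.05)
        assert res.or_point == pytest.approx(4.0)
        assert res.ci_low == pytest.approx(lo, rel=1e-3)
        assert res.ci_high == pytest.approx(hi, rel=1e-3)
        assert (round(res.ci_low, 2), round(res.ci_high, 1)) == (0.55, 29.1)

    def test_zero_cell_names_the_cell(self):
        with pytest.raises(ValueError, match="'c'"):
            crude_or(TwoByTwoTable(a=5, b=5, c=0, d=8))

    def test_or_result_invariants(self):
        with pytest.raises(ValueError):
            ORResult(or_point=1.0, ci_low=1.2, ci_high=2.0)


class TestGroupCompare:
    def test_identical_samples(self):
        t, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        t, p = group_compare([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_matches_reference_welch_implementation(self):
        from statsmodels.stats.weightstats import ttest_ind
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        t, p = group_compare(a, b)
        t_ref, p_ref, _ = ttest_ind(a, b, usevar="unequal")
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_living_alone_rates_differ_significantly(self):
        # deterministic 0/1 vectors with the published group rates
        case = np.r_[np.ones(72), np.zeros(292)]
        control = np.r_[np.ones(460), np.zeros(3106)]
        _, p = group_compare(case, control)
        assert p < 0.05


class TestCorrelationMatrix:
    def test_structure(self, default_city):
        cols = ["older_ages", "living_alone", "not_married", "male"]
        m = correlation_matrix(default_city["cohort"], cols)
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m.values, m.values.T)
        assert (m.values >= -1).all() and (m.values <= 1).all()

    def test_antithetic_pair(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = -df["x"]
        m = correlation_matrix(df)
        assert m.loc["x", "y"] == pytest.approx(-1.0)

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "k": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            correlation_matrix(df)

    def test_height_measures_strongly_correlated(self, default_city):
        m = correlation_matrix(default_city["data"],
                               ["avg_build_height_m", "std_build_height_m"])
        assert abs(m.iloc[0, 1] - 0.82) < 0.15


class TestCompleteCase:
    def test_identity_when_complete(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        kept, n = complete_case_filter(df)
        assert n == 0 and len(kept) == 2

    def test_counts_removed_rows(self):
        df = pd.DataFrame({"a": np.r_[np.nan, np.ones(8), np.nan], "b": np.ones(10)})
        kept, n = complete_case_filter(df)
        assert n == 2 and len(kept) == 8

    def test_all_rows_removed_is_an_error(self):
        with pytest.raises(ValueError):
            complete_case_filter(pd.DataFrame({"a": [np.nan, np.nan]}))


class TestIRLS:
    def test_independent_balanced_predictor_has_null_or(self):
        # equal case rates in both exposure levels -> beta exactly 0
        df = _expand(TwoByTwoTable(a=30, b=30, c=120, d=120))
        fit = fit_logistic_irls(LogisticModelSpec(model_id=0, terms=("exposed",)),
                                df, standardize_activity=False)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)
        assert adjusted_ors(fit)["exposed"].or_point == pytest.approx(1.0, abs=1e-8)

    def test_univariate_fit_equals_crude_or_identity(self):
        """With one binary predictor the MLE slope is exactly the log crude
        OR of the collapsed 2x2 table (algebraic identity)."""
        t = TwoByTwoTable(a=72, b=292, c=460, d=3106)
        fit = fit_logistic_irls(LogisticModelSpec(model_id=0, terms=("exposed",)),
                                _expand(t), standardize_activity=False)
        assert fit.beta[1] == pytest.approx(np.log(crude_or(t).or_point), abs=1e-10)
        assert round(adjusted_ors(fit)["exposed"].or_point, 2) == 1.66

    def test_matches_grid_search_likelihood_oracle(self):
        """On a 20-row toy problem the IRLS optimum matches an iteratively
        refined dense grid search of the Bernoulli likelihood to 1e-3."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        y = (rng.random(20) < 1 / (1 + np.exp(-(0.5 + X[:, 0] - 0.8 * X[:, 1])))).astype(float)

        def loglik(beta):
            eta = beta[0] + X @ beta[1:]
            return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))

        centre, width = np.zeros(3), 8.0
        for _ in range(12):  # 13^3 grid, shrunk around the best point
            axes = [np.linspace(c - width, c + width, 13) for c in centre]
            best, best_ll = None, -np.inf
            for b0 in axes[0]:
                for b1 in axes[1]:
                    for b2 in axes[2]:
                        ll = loglik(np.array([b0, b1, b2]))
                        if ll > best_ll:
                            best, best_ll = np.array([b0, b1, b2]), ll
            centre, width = best, width / 4.0

        est = LogisticRegressionIRLS().fit(X, y)
        np.testing.assert_allclose(est.coef_, centre, atol=1e-3)

    def test_matches_statsmodels_glm(self, default_city):
        import statsmodels.api as sm
        data = default_city["data"]
        terms = list(MODEL_TERMS[3])
        fit = fit_logistic_irls(LogisticModelSpec(model_id=3), data)
        X = data[terms].to_numpy().copy()
        j = terms.index("physical_activity")
        X[:, j] = (X[:, j] - X[:, j].mean()) / X[:, j].std()
        glm = sm.GLM(data["case"].to_numpy(), sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, glm.bse, rtol=1e-4)
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_loglik_monotone_across_iterations(self, default_city):
        fit = fit_logistic_irls(LogisticModelSpec(model_id=3), default_city["data"])
        path = np.array(fit.estimator.loglik_path_)
        assert (np.diff(path) >= -1e-9).all()

    def test_separation_flagged_not_silent(self):
        X = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.warns(UserWarning, match="separation"):
            est = LogisticRegressionIRLS().fit(X, y)
        assert not est.converged_

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            LogisticRegressionIRLS().fit(X, y, feature_names=["x", "x_times_2"])

    def test_requires_both_outcome_classes(self):
        with pytest.raises(ValueError):
            LogisticRegressionIRLS().fit(np.ones((5, 1)), np.ones(5))

    def test_predict_proba_is_a_probability(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 2))
        y = (rng.random(100) < 0.4).astype(float)
        est = LogisticRegressionIRLS().fit(X, y)
        proba = est.predict_proba(X)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_type_one_error_calibration_under_the_null(self):
        """All covariate effects zero: the CI-excludes-1 rejection rate
        pooled over 3 covariates and 500 replicates stays near 5%."""
        rng = np.random.default_rng(2024)
        rejections = trials = 0
        for _ in range(500):
            X = rng.normal(size=(400, 3))
            y = (rng.random(400) < 0.3).astype(float)
            if y.min() == y.max():
                continue
            est = LogisticRegressionIRLS().fit(X, y)
            for j in range(1, 4):
                lo = est.coef_[j] - 1.96 * est.se_[j]
                hi = est.coef_[j] + 1.96 * est.se_[j]
                rejections += not (lo <= 0.0 <= hi)
                trials += 1
        assert 0.03 <= rejections / trials <= 0.07


class TestAdjustedORs:
    def test_closed_form_null_beta(self):
        from geovuln.risk_models import LogisticFit
        fit = LogisticFit(spec=LogisticModelSpec(model_id=0, terms=("z",)),
                          terms=["z"], beta=np.array([0.0, 0.0]),
                          se=np.array([0.0, 0.1]), converged=True,
                          n_used=10, n_removed=0, loglik=0.0)
        res = adjusted_ors(fit)["z"]
        assert res.or_point == pytest.approx(1.0)
        assert round(res.ci_low, 2) == 0.82
        assert round(res.ci_high, 2) == 1.22

    def test_degenerate_ci_with_zero_se(self):
        from geovuln.risk_models import LogisticFit
        fit = LogisticFit(spec=LogisticModelSpec(model_id=0, terms=("z",)),
                          terms=["z"], beta=np.array([0.0, np.log(2.0)]),
                          se=np.array([0.0, 0.0]), converged=True,
                          n_used=10, n_removed=0, loglik=0.0)
        res = adjusted_ors(fit)["z"]
        assert res.or_point == pytest.approx(2.0)
        assert res.ci_low == res.ci_high == pytest.approx(2.0)

    def test_nonconverged_fit_rejected(self):
        from geovuln.risk_models import LogisticFit
        fit = LogisticFit(spec=LogisticModelSpec(model_id=0, terms=("z",)),
                          terms=["z"], beta=np.zeros(2), se=np.zeros(2),
                          converged=False, n_used=10, n_removed=0, loglik=0.0)
        with pytest.raises(ValueError, match="non-converged"):
            adjusted_ors(fit)

    def test_significance_matches_ci_exclusion(self, default_city):
        fit = fit_logistic_irls(LogisticModelSpec(model_id=3), default_city["data"])
        for term, res in adjusted_ors(fit).items():
            assert res.significant == (res.ci_low > 1.0 or res.ci_high < 1.0)


class TestModelSpec:
    def test_named_models_have_confounders(self):
        for m in (1, 2, 3):
            spec = LogisticModelSpec(model_id=m)
            assert "dementia" in spec.terms and "smoking" in spec.terms

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError):
            LogisticModelSpec(model_id=0, terms=("a", "a"))

    def test_term_list_must_match_named_model(self):
        with pytest.raises(ValueError):
            LogisticModelSpec(model_id=1, terms=("older_ages",))
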