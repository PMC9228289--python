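"""OLS fitting, inference tables, stepwise selection, quadratic design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarval import (
    anova,
    build_poly_design,
    coefficient_table,
    fit_metrics,
    fit_ols,
    predict,
    stepwise_select,
)
from qsarval.regression import PolynomialSpec, RankDeficientError, UndefinedMetricError

# Published coefficient table for the six-descriptor GlyT1 model:
# term -> (estimate, SE, t, ci_low, ci_high)
REFERENCE_COEFFICIENTS = {
    "intercept": (-10.408, 3.172, -3.281, -16.905, -3.910),
    "ae": (-0.279, 0.079, -3.550, -0.441, -0.118),
    "gamma": (0.070, 0.033, 2.101, 0.002, 0.138),
    "te": (0.156, 0.042, 3.731, 0.071, 0.242),
    "hbd": (1.830, 0.571, 3.208, 0.661, 2.999),
    "se": (1.716, 0.387, 4.429, 0.922, 2.510),
    "td": (1.030, 0.208, 4.956, 0.604, 1.455),
}


def random_design(seed, n=80, p=4, sigma=0.5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = rng.uniform(-2, 2, size=p + 1)
    y = beta[0] + X.to_numpy() @ beta[1:] + rng.normal(0, sigma, size=n)
    return X, y, beta


class TestFitOls:
    def test_reference_coefficients(self, mlr_model):
        est = dict(zip(mlr_model.term_names, mlr_model.coefficients))
        for term, (ref, *_rest) in REFERENCE_COEFFICIENTS.items():
            assert est[term] == pytest.approx(ref, abs=5e-4), term

    def test_noiseless_fit_is_exact(self):
        X, y, beta = random_design(0, sigma=0.0)
        m = fit_ols(X, y)
        assert m.residuals == pytest.approx(np.zeros(len(y)), abs=1e-9)
        assert fit_metrics(m)["R2"] == pytest.approx(1.0, abs=1e-12)

    def test_simulation_recovery_within_3se(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        beta = np.array([1.0, -0.5, 2.0, 0.3])
        y = beta[0] + X.to_numpy() @ beta[1:] + rng.normal(0, 0.1, size=200)
        table = coefficient_table(fit_ols(X, y))
        z = (table["estimate"].to_numpy() - beta) / table["std_error"].to_numpy()
        assert np.all(np.abs(z) < 3)

    def test_rank_deficient_names_culprit(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(RankDeficientError, match="b"):
            fit_ols(X, np.random.default_rng(0).normal(size=10))

    def test_needs_more_rows_than_parameters(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(4, 4)))
        with pytest.raises(ValueError):
            fit_ols(X, np.zeros(4))


class TestInferenceTables:
    def test_reference_se_t_ci(self, mlr_model):
        table = coefficient_table(mlr_model)
        for term, (_, se, t, lo, hi) in REFERENCE_COEFFICIENTS.items():
            row = table.loc[term]
            assert row["std_error"] == pytest.approx(se, abs=5e-4)
            assert row["t"] == pytest.approx(t, abs=5e-3)
            assert row["ci_low"] == pytest.approx(lo, abs=5e-3)
            assert row["ci_high"] == pytest.approx(hi, abs=5e-3)
            assert row["ci_low"] < row["estimate"] < row["ci_high"]
            assert row["p_value"] <= 0.045

    def test_reference_anova(self, mlr_model):
        a = anova(mlr_model)
        assert a.loc["model", "sum_sq"] == pytest.approx(26.753, abs=1e-3)
        assert a.loc["error", "sum_sq"] == pytest.approx(12.092, abs=1e-3)
        assert a.loc["model", "F"] == pytest.approx(10.325, abs=1e-2)
        assert (a.loc["model", "df"], a.loc["error", "df"]) == (6, 28)

    def test_anova_decomposition_exact(self, mlr_model):
        a = anova(mlr_model)
        assert a.loc["total", "sum_sq"] == pytest.approx(
            a.loc["model", "sum_sq"] + a.loc["error", "sum_sq"], rel=1e-12
        )

    def test_duplicating_rows_raises_f(self, train):
        m1 = fit_ols(train.X, train.y)
        X2 = pd.concat([train.X, train.X], ignore_index=True)
        y2 = np.concatenate([train.y, train.y])
        m2 = fit_ols(X2, y2)
        assert anova(m2).loc["model", "F"] > anova(m1).loc["model", "F"]

    def test_zero_noise_pvalues_vanish(self):
        X, y, _ = random_design(3, sigma=1e-12)
        table = coefficient_table(fit_ols(X, y))
        assert np.all(table["p_value"] < 1e-10)


class TestFitMetrics:
    def test_reference_metrics(self, mlr_model):
        m = fit_metrics(mlr_model)
        assert m["R"] == pytest.approx(0.829884, abs=1e-5)
        assert m["R2"] == pytest.approx(0.688707, abs=1e-5)
        assert m["R2_adj"] == pytest.approx(0.62, abs=5e-3)
        assert m["RMSE"] == pytest.approx(0.66, abs=5e-3)

    def test_r2_equals_squared_correlation(self, mlr_model):
        m = fit_metrics(mlr_model)
        r = np.corrcoef(mlr_model.fitted, mlr_model.y)[0, 1]
        assert m["R2"] == pytest.approx(r**2, abs=1e-10)

    def test_zero_variance_response_rejected(self):
        X = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(UndefinedMetricError):
            fit_metrics(fit_ols(X, np.ones(10)))

    def test_rmse_uses_residual_dof(self, mlr_model):
        # RMSE is the square root of the ANOVA error mean square
        m = fit_metrics(mlr_model)
        a = anova(mlr_model)
        assert m["RMSE"] == pytest.approx(np.sqrt(a.loc["error", "mean_sq"]), rel=1e-12)


class TestStepwise:
    def test_fixture_path_and_postconditions(self, train):
        """Classical forward-backward stepwise on the reference table stalls
        at {te, td} (path dependence: the remaining descriptors only become
        significant jointly), and its output satisfies the selection
        contract: every retained term significant at p_remove, no excluded
        term admissible at p_enter."""
        import statsmodels.api as sm

        kept = stepwise_select(train.X, train.y, p_enter=0.05, p_remove=0.10)
        assert kept == ["te", "td"]
        res = sm.OLS(train.y, sm.add_constant(train.X[kept])).fit()
        assert (res.pvalues.iloc[1:] <= 0.10).all()
        for other in set(train.X.columns) - set(kept):
            res_o = sm.OLS(
                train.y, sm.add_constant(train.X[kept + [other]])
            ).fit()
            assert res_o.pvalues.iloc[-1] > 0.05

    def test_full_six_descriptor_model_all_terms_significant(self, train):
        # the joint model retains all six descriptors at the 5% level,
        # which is why the six-term equation is the reference model
        res = coefficient_table(fit_ols(train.X, train.y))
        assert (res["p_value"].iloc[1:] <= 0.045).all()

    def test_informative_column_found_among_noise(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            rng.normal(size=(100, 10)), columns=[f"n{i}" for i in range(10)]
        )
        X = X.rename(columns={"n0": "signal"})
        y = 2.0 * X["signal"].to_numpy() + rng.normal(0, 0.5, size=100)
        kept = stepwise_select(X, y)
        assert kept == ["signal"]

    def test_p_enter_one_admits_everything(self):
        X, y, _ = random_design(5)
        assert stepwise_select(X, y, p_enter=1.0, p_remove=1.0) == list(X.columns)

    def test_pure_noise_gives_empty_selection(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        with pytest.warns(UserWarning, match="intercept-only"):
            kept = stepwise_select(X, y, p_enter=0.001, p_remove=0.001)
        assert kept == []


class TestPolyDesign:
    def test_auto_prunes_two_level_count_square(self, train):
        Xq, spec = build_poly_design(train.X)
        assert spec.squared_terms == ("ae", "gamma", "te", "se", "td")
        assert Xq.shape[1] == 11
        assert "hbd^2" not in Xq.columns

    def test_binary_column_square_dropped(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0, 1.0], "z": np.arange(5.0)})
        _, spec = build_poly_design(X)
        assert "x" not in spec.squared_terms
        assert "z" in spec.squared_terms

    def test_continuous_columns_all_squared(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.uniform(1, 2, size=(30, 3)), columns=list("abc"))
        _, spec = build_poly_design(X)
        assert spec.squared_terms == ("a", "b", "c")

    def test_explicit_spec_respected(self, train):
        spec = PolynomialSpec(tuple(train.X.columns), ("ae", "td"))
        Xq, _ = build_poly_design(train.X, spec=spec)
        assert list(Xq.columns)[-2:] == ["ae^2", "td^2"]

    def test_spec_rejects_unknown_square(self):
        with pytest.raises(ValueError):
            PolynomialSpec(("a", "b"), ("c",))

    def test_quadratic_model_reference_predictions(self, train, test_set):
        Xq, spec = build_poly_design(train.X)
        m = fit_ols(Xq, train.y)
        assert fit_metrics(m)["R2"] == pytest.approx(0.71, abs=5e-3)
        Xq_test, _ = build_poly_design(test_set.X, spec=spec)
        pred9 = predict(m, Xq_test)[list(test_set.ids).index(9)]
        assert pred9 == pytest.approx(0.380, abs=2e-3)


class TestPredict:
    def test_reference_test_molecule(self, mlr_model, test_set):
        preds = predict(mlr_model, test_set.X)
        assert preds[list(test_set.ids).index(9)] == pytest.approx(0.545, abs=2e-3)

    def test_all_zero_row_returns_intercept(self, mlr_model):
        row = pd.DataFrame([[0.0] * 6], columns=mlr_model.feature_names)
        assert predict(mlr_model, row)[0] == pytest.approx(
            mlr_model.coefficients[0], rel=1e-12
        )

    def test_name_mismatch_rejected(self, mlr_model):
        with pytest.raises(KeyError, match="td"):
            predict(mlr_model, pd.DataFrame({"ae": [40.0]}))


class TestFitInvariants:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_hat_and_residual_properties(self, seed):
        """Hat diagonal sums to K with entries in [1/n, 1]; residuals are
        orthogonal to every design column."""
        X, y, _ = random_design(seed, n=40, p=3)
        m = fit_ols(X, y)
        assert m.hat_diagonal.sum() == pytest.approx(m.K, abs=1e-8)
        assert np.all(m.hat_diagonal >= 1 / m.n - 1e-12)
        assert np.all(m.hat_diagonal <= 1 + 1e-12)
        inner = m.design.to_numpy().T @ m.residuals
        assert inner == pytest.approx(np.zeros(m.K), abs=1e-7)

    def test_ci_coverage_calibrated(self):
        """95% CIs cover the true coefficients 92-98% of the time."""
        rng = np.random.default_rng(2024)
        beta = np.array([0.5, -1.0, 2.0])
        hits = total = 0
        for _ in range(500):
            X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
            y = beta[0] + X.to_numpy() @ beta[1:] + rng.normal(0, 1.0, size=50)
            t = coefficient_table(fit_ols(X, y))
            hits += int(
                ((t["ci_low"].to_numpy() <= beta) & (beta <= t["ci_high"].to_numpy())).sum()
            )
            total += 3
        assert 0.92 <= hits / total <= 0.98
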