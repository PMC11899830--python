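"""Statistical battery: MLC screening, MLR, LOOCV, polynomial models."""

import math

import numpy as np
import pandas as pd
import pytest

from conntopo import (DescriptorSpec, QsprError, descriptor_table, fit_mlr,
                      fit_polynomial, loocv_rmse, multiple_correlation,
                      r2_grid, rank_by_mlc, screening_report)


def pearson(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def mlc_closed_form(y, x1, x2):
    """Pairwise-correlation closed form of the multiple correlation."""
    ry1, ry2, r12 = pearson(y, x1), pearson(y, x2), pearson(x1, x2)
    return math.sqrt((ry1 ** 2 + ry2 ** 2 - 2 * ry1 * ry2 * r12) / (1 - r12 ** 2))


def hat_matrix_loocv(y, X):
    """Independent LOOCV shortcut: residual over one minus leverage."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    press = resid / (1.0 - np.diag(H))
    return float(np.sqrt(np.mean(press ** 2)))


@pytest.fixture(scope="module")
def bh_screen(bh22_published):
    """Properties plus printed reference descriptor columns (floats)."""
    props = bh22_published.properties
    printed = bh22_published.printed.astype(float)
    return props["bp"].to_numpy(), props["hf"].to_numpy(), printed


class TestMultipleCorrelation:
    @pytest.mark.parametrize("column,expected", [
        ("Mc1", 0.9138), ("Mc2", 0.8938), ("Pc1", 0.6783), ("Pc2", 0.6793),
    ])
    def test_printed_reference_columns(self, bh_screen, column, expected):
        """The four published reference descriptor columns reproduce the
        published screening correlations at 4 decimal places."""
        x1, x2, printed = bh_screen
        res = multiple_correlation(printed[column].to_numpy(), x1, x2)
        assert res.n == 22
        assert round(res.rho, 4) == expected

    def test_perfect_linear_dependence(self, bh_screen):
        x1, x2, _ = bh_screen
        assert multiple_correlation(x1, x1, x2).rho == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_ols_route_equals_pairwise_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(size=8), rng.normal(size=8)
        y = 1.5 * x1 - 0.7 * x2 + rng.normal(size=8)
        res = multiple_correlation(y, x1, x2)
        assert res.rho == pytest.approx(mlc_closed_form(y, x1, x2), abs=1e-10)

    def test_error_conditions(self):
        with pytest.raises(QsprError, match="4 samples"):
            multiple_correlation([1, 2, 3], [1, 2, 3], [3, 2, 1])
        with pytest.raises(QsprError, match="zero variance"):
            multiple_correlation([5, 5, 5, 5], [1, 2, 3, 4], [4, 1, 2, 3])
        with pytest.raises(QsprError, match="collinear"):
            multiple_correlation([1, 2, 3, 5], [1, 2, 3, 4], [2, 4, 6, 8])


class TestFitMLR:
    def test_reproduces_published_model_statistics(self, bh22_published):
        """The top descriptor's two-property OLS model matches the published
        r-squared and standard error at printed precision, and the MLC and
        MLR routes agree on r^2."""
        desc = descriptor_table(bh22_published.graphs)
        y = desc["SCC_B-1"].to_numpy(dtype=float)
        x1 = bh22_published.properties["bp"].to_numpy()
        x2 = bh22_published.properties["hf"].to_numpy()
        fit = fit_mlr(y, [x1, x2], term_names=("bp", "hf"))
        assert round(fit.r_squared, 4) == 0.8716
        assert round(fit.s, 4) == 0.2644
        assert round(float(fit.coefficients[0]), 4) == 0.8551
        assert round(float(fit.ci95[0]), 4) == 0.4702
        assert round(float(fit.coefficients[1]), 4) == 0.0018
        assert round(float(fit.ci95[1]), 4) == 0.0033
        rho = multiple_correlation(y, x1, x2).rho
        assert rho ** 2 == pytest.approx(fit.r_squared, abs=1e-12)
        assert "r^2 = 0.8716" in fit.summary()

    def test_exact_affine_response(self):
        x1 = np.arange(8.0)
        x2 = np.array([3, 1, 4, 1, 5, 9, 2, 6.0])
        y = 2.0 + 3.0 * x1 - 0.5 * x2
        fit = fit_mlr(y, [x1, x2])
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.s == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # tiny n=5, p=2 problem solved independently via the normal equations
        x1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x2 = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        y = np.array([3.1, 4.9, 7.2, 8.8, 13.0])
        X = np.column_stack([np.ones(5), x1, x2])
        expected = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_mlr(y, [x1, x2])
        assert fit.coefficients == pytest.approx(expected, abs=1e-10)

    def test_sample_size_and_rank_guards(self):
        with pytest.raises(QsprError, match="n > p"):
            fit_mlr([1, 2, 3], [[1, 2, 3], [3, 1, 2]])
        with pytest.raises(QsprError, match="rank-deficient"):
            fit_mlr([1, 2, 3, 4, 5], [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10]])

    def test_f_statistic_definition(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(size=10), rng.normal(size=10)
        y = x1 + rng.normal(size=10)
        fit = fit_mlr(y, [x1, x2])
        expected = (fit.r_squared / 2) / ((1 - fit.r_squared) / (fit.n - 3))
        assert fit.f == pytest.approx(expected, rel=1e-10)


class TestLoocv:
    def test_reproduces_published_rmse(self, bh22_published):
        desc = descriptor_table(bh22_published.graphs)
        y = desc["SCC_B-1"].to_numpy(dtype=float)
        x1 = bh22_published.properties["bp"].to_numpy()
        x2 = bh22_published.properties["hf"].to_numpy()
        assert round(loocv_rmse(y, [x1, x2]).loocv_rmse, 4) == 0.2800

    def test_affine_response_gives_zero(self):
        x1 = np.arange(8.0)
        x2 = np.array([3, 1, 4, 1, 5, 9, 2, 6.0])
        y = 1.0 + 2.0 * x1 + 0.25 * x2
        assert loocv_rmse(y, [x1, x2]).loocv_rmse == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_refit_loop_agrees_with_hat_matrix_shortcut(self, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.normal(size=6), rng.normal(size=6)
        y = x1 - x2 + rng.normal(size=6)
        got = loocv_rmse(y, [x1, x2]).loocv_rmse
        X = np.column_stack([np.ones(6), x1, x2])
        assert got == pytest.approx(hat_matrix_loocv(y, X), abs=1e-10)

    def test_too_small_sample_rejected(self):
        with pytest.raises(QsprError, match="n > p"):
            loocv_rmse([1, 2, 3, 4], [[1, 2, 3, 4], [4, 2, 1, 3]])


class TestFitPolynomial:
    def test_exact_quadratic_recovery(self):
        x = np.linspace(-2, 3, 9)
        y = 1.5 - 2.0 * x + 0.75 * x ** 2
        fit = fit_polynomial(y, x, 2)
        assert fit.coefficients == pytest.approx([1.5, -2.0, 0.75], abs=1e-8)
        assert fit.r == pytest.approx(1.0, abs=1e-10)

    def test_degree_one_matches_simple_regression_formulas(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 3.5, 6.0, 11.5])
        fit = fit_polynomial(y, x, 1)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.coefficients == pytest.approx([intercept, slope], abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(QsprError, match="distinct"):
            fit_polynomial([1, 2, 3, 4, 5], [1, 1, 2, 2, 1], 2)
        with pytest.raises(QsprError, match="degree"):
            fit_polynomial([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6], 4)


class TestRanking:
    def test_published_screening_table_yields_published_top_five(self):
        """Ranking the 21 published screening correlations reproduces the
        published top-five list and ordering."""
        table12 = {
            "MC1": 0.9138, "MC2": 0.8938, "PC1": 0.6783, "PC2": 0.6793,
            "RC": 0.7947, "RC_B1": 0.8938, "RC_B-1": 0.9164, "RC_B2": 0.8412,
            "RC_B-2": 0.7950, "SCC": 0.9318, "SCC_B1": 0.9138,
            "SCC_B-1": 0.9336, "SCC_B2": 0.8927, "SCC_B-2": 0.9140,
            "ABCC": 0.9310, "AZIC": 0.8892, "GAC": 0.9279, "AGC": 0.9272,
            "RRC": 0.9143, "RRRC": 0.9097, "SOC": 0.9132,
        }
        from conntopo import MLCResult, spec_from_name
        results = [MLCResult(spec_from_name(k), rho, 22) for k, rho in table12.items()]
        top = rank_by_mlc(results, 5)
        assert [r.label for r in top] == ["SCC_B-1", "SCC", "ABCC", "GAC", "AGC"]

    def test_tie_broken_by_registry_order(self):
        from conntopo import MLCResult
        a = MLCResult(DescriptorSpec("SOC"), 0.9, 10)
        b = MLCResult(DescriptorSpec("MC1"), 0.9, 10)
        assert [r.label for r in rank_by_mlc([a, b], 2)] == ["MC1", "SOC"]

    def test_single_result_and_oversized_k(self):
        from conntopo import MLCResult
        only = MLCResult(DescriptorSpec("MC1"), 0.5, 10)
        assert rank_by_mlc([only], 1) == [only]
        with pytest.warns(UserWarning, match="exceeds"):
            assert rank_by_mlc([only], 3) == [only]


class TestR2Grid:
    @pytest.fixture()
    def synthetic(self):
        rng = np.random.default_rng(7)
        idx = [f"c{i}" for i in range(12)]
        x = rng.uniform(1, 5, size=12)
        desc = pd.DataFrame({"D1": x, "D2": x ** 1.5 + rng.normal(0, 0.1, 12)}, index=idx)
        props = pd.DataFrame({
            "affine": 2 + 3 * x,
            "noisy": np.sin(x) + rng.normal(0, 0.3, 12),
        }, index=idx)
        return props, desc

    def test_cardinality(self, synthetic):
        props, desc = synthetic
        grid = r2_grid(props, desc)
        assert sorted(grid.tables) == [1, 2, 3]
        assert all(t.shape == (2, 2) for t in grid.tables.values())

    def test_affine_column_saturates_all_degrees(self, synthetic):
        props, desc = synthetic
        grid = r2_grid(props, desc)
        for d in (1, 2, 3):
            assert grid.tables[d].loc["D1", "affine"] == pytest.approx(1.0, abs=1e-10)

    def test_nested_models_never_lose_r2(self, synthetic):
        props, desc = synthetic
        grid = r2_grid(props, desc)
        for dname in desc.columns:
            for pname in props.columns:
                r1 = grid.tables[1].loc[dname, pname]
                r2v = grid.tables[2].loc[dname, pname]
                r3 = grid.tables[3].loc[dname, pname]
                assert r1 <= r2v + 1e-12 <= r3 + 2e-12

    def test_misaligned_compounds_rejected(self, synthetic):
        props, desc = synthetic
        with pytest.raises(QsprError, match="misaligned"):
            r2_grid(props.iloc[:-1], desc)


class TestScreeningReport:
    def test_full_battery_shapes(self, bh22_published):
        desc = descriptor_table(bh22_published.graphs)
        rep = screening_report(desc, bh22_published.properties,
                               poly_degrees=(1, 2, 3))
        assert len(rep["mlc"]) == 21
        assert len(rep["ranking"]) == 5
        assert list(rep["mlr"].index) == list(rep["ranking"]["descriptor"])
        assert rep["r2_degree1"].shape == (21, 2)
        assert round(rep["loocv"].loc["SCC_B-1", "loocv_rmse"], 4) == 0.2800
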