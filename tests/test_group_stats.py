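"""Design building, GLM fits, p correction, CIs, Bayes factors,
collinearity screening, outlier screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import froikit as fk
from froikit.group_stats import (CollinearityReport, FULL_PREDICTORS,
                                 PerfectSeparationError, belsley,
                                 build_design, conf_interval, correct_p,
                                 fit_binomial_glm, fit_gaussian_glm,
                                 jzs_bf01, outlier_screen)


@pytest.fixture(scope="module")
def cohort():
    return fk.generate_cohort(fk.CohortConfig(n_nt=80, n_asd=20,
                                              iq_fraction_nt=1.0),
                              seed=1).set_index("id", drop=False)


class TestBuildDesign:
    def test_full_predictor_list_gives_nine_columns(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS)
        assert len(design.columns) == 9  # 8 predictors + intercept
        assert design.columns[0] == "intercept"

    def test_degenerate_column_excluded(self, cohort):
        single_coil = cohort.assign(coil="12ch")
        design = build_design(single_coil, FULL_PREDICTORS)
        assert "coil" in design.dropped_columns
        assert "coil" not in design.columns

    def test_non_intercept_columns_centered(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS)
        means = design.frame.drop(columns="intercept").mean()
        assert np.all(np.abs(means) < 1e-10)
        assert np.all(design.frame["intercept"] == 1.0)

    def test_rows_with_missing_values_dropped(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS + ("iq",))
        assert len(design.frame) == cohort.iq.notna().sum()
        assert set(design.dropped_rows) == set(cohort.index[cohort.iq.isna()])

    def test_dummy_task_coding_option(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS, task_coding="dummy")
        assert {"task_FITB", "task_MTS"} <= set(design.columns)
        assert "task_type" not in design.columns


class TestGaussianGlm:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.normal(size=30)})
        frame["group"] = np.repeat(["NT", "ASD"], 15)
        design = build_design(frame, ("x",))
        y = 2.0 * frame["x"]
        fits = fit_gaussian_glm(y, design, frame)
        assert fits["x"].beta == pytest.approx(2.0, abs=1e-10)

    def test_single_binary_predictor_beta_is_group_mean_difference(self):
        frame = pd.DataFrame({"group": ["NT"] * 6 + ["ASD"] * 4})
        design = build_design(frame, ("group",))
        y = pd.Series([1.0, 2, 3, 4, 5, 6, 10, 11, 12, 13])
        fits = fit_gaussian_glm(y, design, frame)
        assert fits["group"].beta == pytest.approx(11.5 - 3.5)

    def test_matches_normal_equations_oracle(self):
        """OLS coefficients equal (X'X)^-1 X'y on random problems."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            frame = pd.DataFrame(rng.normal(size=(50, 3)),
                                 columns=["a", "b", "c"])
            design = build_design(frame, ("a", "b", "c"))
            y = rng.normal(size=50)
            fits = fit_gaussian_glm(y, design, frame)
            X = design.values
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            for i, name in enumerate(("a", "b", "c"), start=1):
                assert fits[name].beta == pytest.approx(beta[i], abs=1e-10)

    def test_df_is_n_minus_columns(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS)
        y = np.arange(len(design.frame), dtype=float)
        fits = fit_gaussian_glm(y, design, cohort)
        assert fits["group"].df == len(design.frame) - 9

    def test_missing_y_dropped_listwise(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=len(design.frame)),
                      index=design.index)
        y.iloc[:10] = np.nan
        fits = fit_gaussian_glm(y, design, cohort)
        assert fits["group"].df == len(design.frame) - 10 - 9

    def test_rank_deficient_design_raises(self, cohort):
        design = build_design(cohort, FULL_PREDICTORS)
        design.frame["dup"] = design.frame["age"]
        y = np.arange(len(design.frame), dtype=float)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_gaussian_glm(y, design, cohort)


class TestBinomialGlm:
    def test_two_by_two_table_log_odds(self):
        frame = pd.DataFrame({"x": [0.0] * 30 + [1.0] * 30})
        found = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        design = build_design(frame, ("x",))
        fits = fit_binomial_glm(found, design, frame)
        assert fits["x"].beta == pytest.approx(-np.log(4.0), abs=1e-6)

    def test_balanced_intercept_near_zero(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame({"x": rng.normal(size=200)})
        found = rng.integers(0, 2, 200).astype(float)
        design = build_design(frame, ("x",))
        fits = fit_binomial_glm(found, design, frame)
        # Wald p against the standard normal, not the t
        f = fits["x"]
        assert f.p_uncorrected == pytest.approx(
            2 * stats.norm.sf(abs(f.statistic)), abs=1e-12)

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"x": np.arange(10.0)})
        design = build_design(frame, ("x",))
        with pytest.raises(ValueError, match="single class"):
            fit_binomial_glm(np.ones(10), design, frame)

    def test_perfect_separation_raises(self):
        frame = pd.DataFrame({"x": np.arange(20.0)})
        found = (frame["x"] > 9.5).astype(float).to_numpy()
        design = build_design(frame, ("x",))
        with pytest.raises(PerfectSeparationError):
            fit_binomial_glm(found, design, frame)


class TestCorrectP:
    @pytest.mark.parametrize("p,m,expected", [
        (0.5, 1, 0.5),
        (0.1, 2, 0.19),
        (1.0, 10, 1.0),
    ])
    def test_formula_values(self, p, m, expected):
        assert correct_p(p, m) == pytest.approx(expected)

    def test_monotone_in_p_and_m(self):
        ps = np.linspace(0, 1, 11)
        out = correct_p(ps, 6)
        assert np.all(np.diff(out) >= 0)
        assert correct_p(0.2, 3) <= correct_p(0.2, 6)

    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 100))
    @settings(deadline=None, max_examples=200)
    def test_output_bounded_and_identity_at_m_one(self, p, m):
        out = correct_p(p, m)
        assert 0.0 <= out <= 1.0
        assert out >= p - 1e-12
        assert correct_p(p, 1) == pytest.approx(p)


class TestConfInterval:
    def test_published_style_lower_bound(self):
        low, high = conf_interval(0.101, 1.030, 455)
        assert low == pytest.approx(-0.153, abs=5e-4)

    def test_zero_beta_symmetric(self):
        low, high = conf_interval(0.0, 1.0, 50)
        assert low == pytest.approx(-high)

    def test_level_zero_degenerate(self):
        assert conf_interval(0.3, 2.0, 50, level=0.0) == (0.3, 0.3)

    def test_coverage_on_simulated_ols(self):
        """99% CI from (beta, t) covers the true coefficient ~99% of
        the time."""
        rng = np.random.default_rng(5)
        cover = 0
        n_sim = 600
        for _ in range(n_sim):
            x = rng.normal(size=40)
            y = 1.5 * x + rng.normal(size=40)
            X = np.column_stack([np.ones(40), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / 38
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            low, high = conf_interval(beta[1], beta[1] / se, 38)
            cover += low <= 1.5 <= high
        assert cover / n_sim == pytest.approx(0.99, abs=0.015)


def jzs_bf01_grid_oracle(t, n1, n2, df, r=1.0, n_grid=400001):
    """Fixed-grid trapezoid quadrature of the same integral, with the
    compactifying substitution g = z/(1-z) so the full (0, inf) range
    is covered (no tail truncation)."""
    N = n1 * n2 / (n1 + n2)
    z = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = z / (1 - z)
    log_f = (-0.5 * np.log1p(N * g)
             - (df + 1) / 2.0 * np.log1p(t * t / ((1 + N * g) * df))
             - 0.5 * np.log(2 * np.pi) + np.log(r)
             - 1.5 * np.log(g) - r * r / (2 * g))
    jac = 1.0 / (1 - z) ** 2
    num = np.trapezoid(np.exp(log_f) * jac, z)
    den = (1 + t * t / df) ** (-(df + 1) / 2.0)
    return den / num


class TestJzsBayesFactor:
    def test_agrees_with_fixed_grid_quadrature(self):
        for t, n1, n2, df in [(1.030, 436, 28, 455), (0.255, 418, 28, 437),
                              (2.5, 30, 30, 58), (0.8, 100, 15, 110)]:
            mine = jzs_bf01(t, n1, n2, df)
            oracle = jzs_bf01_grid_oracle(t, n1, n2, df)
            assert mine == pytest.approx(oracle, rel=5e-4)

    def test_strictly_decreasing_in_abs_t(self):
        ts = np.linspace(0.0, 4.0, 9)
        bfs = [jzs_bf01(t, 50, 20, 68) for t in ts]
        assert np.all(np.diff(bfs) < 0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 0, 10, 20)
        with pytest.raises(ValueError):
            jzs_bf01(1.0, 10, 10, 0)


class TestBelsley:
    def test_orthonormal_columns_clean(self):
        X = np.eye(10)[:, :4]
        report = belsley(X)
        assert np.allclose(report.condition_indices, 1.0)
        assert report.flags == []

    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        X = np.column_stack([np.ones(20), x, x * (1 + 1e-12)])
        report = belsley(X)
        assert report.condition_indices[-1] > 1e5
        flagged = {name for name, _ in report.flags}
        assert {"x1", "x2"} <= flagged

    def test_proportions_match_direct_svd_arithmetic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 5))
        report = belsley(X)
        scaled = X / np.linalg.norm(X, axis=0)
        _, s, vt = np.linalg.svd(scaled, full_matrices=False)
        phi = (vt.T ** 2) / s ** 2
        expected = phi / phi.sum(axis=1, keepdims=True)
        assert np.allclose(report.proportions.to_numpy(), expected)
        assert np.allclose(report.proportions.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diff(report.condition_indices) >= 0)

    def test_zero_column_rejected(self):
        X = np.column_stack([np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError, match="zero column"):
            belsley(X)


class TestOutlierScreen:
    def test_typical_values_not_flagged(self):
        values = np.r_[np.random.default_rng(8).normal(size=50), [0.0] * 5]
        groups = ["NT"] * 50 + ["ASD"] * 5
        assert len(outlier_screen(values, groups)) == 0

    def test_four_sd_value_flagged(self):
        rng = np.random.default_rng(9)
        nt = rng.normal(size=100)
        values = np.r_[nt, [nt.mean() + 4 * nt.std(ddof=1)]]
        groups = ["NT"] * 100 + ["ASD"]
        assert len(outlier_screen(values, groups)) == 1

    def test_null_rate_matches_binomial_expectation(self):
        """Under a shared normal distribution the expected flag count is
        n_asd * P(|z| > 3)."""
        rng = np.random.default_rng(10)
        counts = [len(outlier_screen(
            np.r_[rng.normal(size=200), rng.normal(size=31)],
            ["NT"] * 200 + ["ASD"] * 31)) for _ in range(200)]
        expected = 31 * 2 * stats.norm.sf(3)
        se = np.sqrt(expected / 200)  # Poisson-ish MC error
        assert abs(np.mean(counts) - expected) < 4 * se + 0.05

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            outlier_screen([1.0, 1.0, 2.0], ["NT", "NT", "ASD"])
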