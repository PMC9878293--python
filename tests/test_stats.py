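"""Reliability and association statistics against independent oracles.

Each statistic is checked two ways: against a from-scratch textbook-formula
computation written in this file, and (for alpha and the ICCs) against
pingouin as an independent library implementation.
"""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import scipy.stats

from revcorr import (
    CollinearityError,
    DegenerateDataError,
    InputError,
    RatingMatrix,
    correlation_matrix,
    cronbach_alpha,
    icc,
    paired_t,
    pearson_r,
    standardized_ols,
)

# ---------------------------------------------------------------- oracles


def alpha_oracle(x: np.ndarray) -> float:
    """Long-form variance sums."""
    n, k = x.shape
    totals = x.sum(axis=1)
    var_total = ((totals - totals.mean()) ** 2).sum() / (n - 1)
    var_items = sum(((x[:, j] - x[:, j].mean()) ** 2).sum() / (n - 1) for j in range(k))
    return k / (k - 1) * (1 - var_items / var_total)


def icc_oracle(x: np.ndarray, form: str) -> float:
    """Two-way ANOVA sums of squares computed with explicit loops."""
    n, k = x.shape
    g = x.mean()
    ss_r = sum(k * (x[i].mean() - g) ** 2 for i in range(n))
    ss_c = sum(n * (x[:, j].mean() - g) ** 2 for j in range(k))
    ss_t = sum((x[i, j] - g) ** 2 for i in range(n) for j in range(k))
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = (ss_t - ss_r - ss_c) / ((n - 1) * (k - 1))
    if form == "3k":
        return (msr - mse) / msr
    return (msr - mse) / (msr + (msc - mse) / n)


def pearson_oracle(x, y):
    cx, cy = x - x.mean(), y - y.mean()
    r = (cx * cy).sum() / np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    n = x.size
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * scipy.stats.t.sf(abs(t), n - 2)
    return r, p


def ols_oracle(y, X):
    """Normal equations on z-scored data; dof = n - p - 1."""
    n, p = X.shape
    zX = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    xtx = zX.T @ zX
    beta = np.linalg.solve(xtx, zX.T @ zy)
    resid = zy - zX @ beta
    s2 = resid @ resid / (n - p - 1)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(xtx)))
    t = beta / se
    pvals = 2 * scipy.stats.t.sf(np.abs(t), n - p - 1)
    return beta, t, pvals


# ---------------------------------------------------------------- alpha


class TestCronbachAlpha:
    def test_identical_columns_alpha_one(self):
        col = np.array([1.0, 3.0, 5.0, 7.0])
        assert cronbach_alpha(np.column_stack([col] * 4)) == pytest.approx(1.0)

    def test_negatively_related_columns_alpha_nonpositive(self):
        """Near-mirror columns: covariance is negative, so alpha <= 0.
        (Exactly mirrored columns make the total score constant, which is
        the degenerate zero-variance case below.)"""
        x = np.array([[1.0, 9.0], [3.0, 7.0], [7.0, 3.0], [9.0, 2.0]])
        assert cronbach_alpha(x) <= 0
        assert cronbach_alpha(x) == pytest.approx(alpha_oracle(x), abs=1e-12)

    def test_integer_fixture_matches_long_form_oracle(self):
        x = np.array(
            [[3, 4, 5], [2, 2, 3], [5, 5, 4], [1, 2, 1], [4, 3, 5]], dtype=float
        )
        assert cronbach_alpha(x) == pytest.approx(alpha_oracle(x), abs=1e-12)

    def test_matches_pingouin_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.integers(1, 10, (8, 5)).astype(float)
            if x.sum(axis=1).var(ddof=1) == 0:
                continue
            assert cronbach_alpha(x) == pytest.approx(
                pg.cronbach_alpha(data=pd.DataFrame(x))[0], abs=1e-10
            )

    def test_reverse_keyed_column_recoded_first(self):
        rng = np.random.default_rng(3)
        base = rng.integers(2, 9, (10, 4)).astype(float)
        flipped = base.copy()
        flipped[:, 1] = 10.0 - flipped[:, 1]
        m = RatingMatrix(flipped, scale_min=1, scale_max=9, reverse_keyed=frozenset({1}))
        assert cronbach_alpha(m) == pytest.approx(cronbach_alpha(base), abs=1e-12)

    def test_zero_total_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(np.array([[1.0, 2.0], [2.0, 1.0], [1.0, 2.0], [2.0, 1.0]]))


# ---------------------------------------------------------------- icc


class TestICC:
    def test_identical_raters_give_one(self):
        col = np.array([2.0, 4.0, 6.0, 8.0, 5.0])
        x = np.column_stack([col] * 3)
        assert icc(x, "3k").estimate == pytest.approx(1.0)
        assert icc(x, "2k").estimate == pytest.approx(1.0)

    def test_constant_rater_offsets(self):
        """Offset-only disagreement: perfect consistency, imperfect agreement."""
        col = np.array([2.0, 4.0, 6.0, 8.0, 5.0])
        x = np.column_stack([col, col + 1, col + 3])
        assert icc(x, "3k").estimate == pytest.approx(1.0)
        assert icc(x, "2k").estimate < 1.0

    def test_matches_loop_anova_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(5, 2, (6, 3))
        for form in ("2k", "3k"):
            assert icc(x, form).estimate == pytest.approx(icc_oracle(x, form), abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(6)
        x = rng.integers(1, 10, (8, 4)).astype(float)
        long = pd.DataFrame(
            {
                "target": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "score": x.ravel(),
            }
        )
        pg_icc = pg.intraclass_corr(long, targets="target", raters="rater",
                                    ratings="score").set_index("Type")
        # McGraw-Wong labels: (A,k) = absolute agreement = ICC(2,k);
        # (C,k) = consistency = ICC(3,k)
        assert icc(x, "2k").estimate == pytest.approx(pg_icc.loc["ICC(A,k)", "ICC"], abs=1e-10)
        assert icc(x, "3k").estimate == pytest.approx(pg_icc.loc["ICC(C,k)", "ICC"], abs=1e-10)

    def test_3k_at_least_2k_when_raters_disagree_systematically(self):
        """ICC(2,k) additionally penalizes between-rater level differences,
        so ICC(3,k) >= ICC(2,k) exactly when MS_cols >= MS_error (the
        denominators differ by (MS_cols - MS_error)/n).  Checked both as an
        implication on random data and directly on offset-heavy data."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(0, 1, (5, 3)) + rng.normal(0, 1, (5, 1))
            res2, res3 = icc(x, "2k"), icc(x, "3k")
            if res2.ms_cols >= res2.ms_error:
                assert res3.estimate >= res2.estimate - 1e-12
        for _ in range(20):
            x = rng.normal(0, 0.3, (6, 3)) + rng.normal(0, 1, (6, 1)) + rng.normal(0, 2, (1, 3))
            assert icc(x, "3k").estimate >= icc(x, "2k").estimate - 1e-12

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(5, 1, (7, 3))
        perm = rng.permutation(7)
        assert icc(x, "2k").estimate == pytest.approx(icc(x[perm], "2k").estimate, abs=1e-12)

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(InputError):
            icc(x, "2k")


# ---------------------------------------------------------------- pearson / t


class TestPearson:
    def test_affine_gives_unit_correlation(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 3).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_covariance_ratio_oracle(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r_o, p_o = pearson_oracle(x, y)
        res = pearson_r(x, y)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)
        assert res.n == 10

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateDataError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestPairedT:
    def test_matches_mean_se_formula(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 30)
        y = x - rng.normal(0, 1, 30)
        d = x - y
        t_o = d.mean() / (d.std(ddof=1) / np.sqrt(30))
        res = paired_t(x, y)
        assert res.t == pytest.approx(t_o, abs=1e-12)
        assert res.dof == 29
        assert res.p == pytest.approx(2 * scipy.stats.t.sf(abs(t_o), 29), abs=1e-12)

    def test_swap_negates_t(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert paired_t(x, y).t == -paired_t(y, x).t

    def test_ci_coverage_of_true_shift(self):
        """95% CI of the mean difference contains the true shift at the
        nominal rate (binomial tolerance at 500 simulations)."""
        rng = np.random.default_rng(13)
        shift, hits, n_sim = 0.7, 0, 500
        for _ in range(n_sim):
            y = rng.normal(0, 1, 20)
            x = y + shift + rng.normal(0, 1, 20)
            lo, hi = paired_t(x, y).ci
            hits += lo <= shift <= hi
        se = np.sqrt(0.95 * 0.05 / n_sim)
        assert abs(hits / n_sim - 0.95) < 4 * se

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t(np.arange(5.0), np.arange(5.0) + 2.0)


# ---------------------------------------------------------------- ols


class TestStandardizedOLS:
    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        res = standardized_ols(y, x)
        assert res.standardized_betas[0] == pytest.approx(pearson_r(y, x).r, abs=1e-12)
        assert res.dof == 38

    def test_orthogonal_predictors_betas_are_marginal_correlations(self):
        n = 32
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)  # orthogonal and centered
        rng = np.random.default_rng(15)
        y = 0.8 * x1 - 0.3 * x2 + rng.normal(0, 0.5, n)
        res = standardized_ols(y, np.column_stack([x1, x2]))
        for j, x in enumerate([x1, x2]):
            assert res.standardized_betas[j] == pytest.approx(pearson_r(y, x).r, abs=1e-10)

    def test_two_correlated_predictors_closed_form(self):
        """beta_1 = (r_y1 - r_y2 r_12) / (1 - r_12^2)."""
        rng = np.random.default_rng(16)
        x1 = rng.normal(size=60)
        x2 = 0.6 * x1 + rng.normal(0, 0.8, 60)
        y = x1 + 0.5 * x2 + rng.normal(0, 1, 60)
        r_y1, r_y2 = pearson_r(y, x1).r, pearson_r(y, x2).r
        r_12 = pearson_r(x1, x2).r
        res = standardized_ols(y, np.column_stack([x1, x2]))
        assert res.standardized_betas[0] == pytest.approx(
            (r_y1 - r_y2 * r_12) / (1 - r_12 ** 2), abs=1e-10
        )
        assert res.standardized_betas[1] == pytest.approx(
            (r_y2 - r_y1 * r_12) / (1 - r_12 ** 2), abs=1e-10
        )

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(25, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=25)
        beta_o, t_o, p_o = ols_oracle(y, X)
        res = standardized_ols(y, X)
        np.testing.assert_allclose(res.standardized_betas, beta_o, atol=1e-10)
        np.testing.assert_allclose(res.t_statistics, t_o, atol=1e-10)
        np.testing.assert_allclose(res.p_values, p_o, atol=1e-10)
        assert res.dof == 25 - 3 - 1

    def test_collinearity_named(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=20)
        with pytest.raises(CollinearityError, match="a~b"):
            standardized_ols(rng.normal(size=20), np.column_stack([x, 2 * x]),
                             names=["a", "b"])


def test_correlation_matrix_symmetry_and_values():
    rng = np.random.default_rng(19)
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
    r, p = correlation_matrix(df)
    assert np.allclose(r.values, r.values.T)
    assert r.loc["a", "b"] == pytest.approx(pearson_r(df["a"], df["b"]).r, abs=1e-12)
    assert p.loc["a", "c"] == pytest.approx(pearson_r(df["a"], df["c"]).p, abs=1e-12)


def test_rating_matrix_bounds_enforced():
    with pytest.raises(InputError):
        RatingMatrix(np.array([[0.0, 5.0], [3.0, 4.0]]), scale_min=1, scale_max=9)
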