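"""Reliability and association statistics for rating and score data.

Covers the statistics a reverse-correlation validity study leans on:
Cronbach's alpha for internal consistency of multi-item scales, two-way
intraclass correlations ICC(2,k) (absolute agreement) and ICC(3,k)
(consistency) for averaged-rater reliability, Pearson correlations with
two-tailed p, paired t-tests, and multiple regression reported as
standardized coefficients (beta weights).

Alpha and the ICC ANOVA decomposition are computed from their defining
variance formulas (the result types expose the mean squares); correlation,
t-test and OLS machinery delegates to scipy / statsmodels.  All p-values
are two-tailed and no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import CollinearityError, DegenerateDataError, InputError

__all__ = [
    "RatingMatrix",
    "ICCResult",
    "RegressionResult",
    "PearsonResult",
    "PairedTResult",
    "cronbach_alpha",
    "icc",
    "pearson_r",
    "paired_t",
    "standardized_ols",
    "mean_ci",
    "correlation_matrix",
]


@dataclass
class RatingMatrix:
    """Targets x raters (or respondents x items) rating matrix.

    ``reverse_keyed`` columns are recoded as ``scale_min + scale_max - x``
    before any statistic is computed.
    """

    values: np.ndarray
    scale_min: float = 1.0
    scale_max: float = 9.0
    reverse_keyed: frozenset[int] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InputError(f"rating matrix must be 2-D, got shape {self.values.shape}")
        self.reverse_keyed = frozenset(int(i) for i in self.reverse_keyed)
        if np.isnan(self.values).any():
            raise InputError("rating matrix contains missing cells; complete data required "
                             "(listwise deletion is the caller's responsibility)")
        if self.values.min() < self.scale_min or self.values.max() > self.scale_max:
            raise InputError(
                f"ratings outside declared scale [{self.scale_min}, {self.scale_max}]"
            )
        bad = [i for i in self.reverse_keyed if i >= self.values.shape[1]]
        if bad:
            raise InputError(f"reverse_keyed column indices out of range: {bad}")

    def recoded(self) -> np.ndarray:
        """Return values with reverse-keyed columns recoded."""
        out = self.values.copy()
        for i in self.reverse_keyed:
            out[:, i] = self.scale_min + self.scale_max - out[:, i]
        return out


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, RatingMatrix):
        return data.recoded()
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D matrix, got shape {arr.shape}")
    if np.isnan(arr).any():
        raise InputError("matrix contains missing cells")
    return arr


def cronbach_alpha(data: RatingMatrix | np.ndarray) -> float:
    """Cronbach's alpha of a respondents x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with n-1 sample variances.
    """
    x = _as_matrix(data)
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"alpha needs >= 2 rows and >= 2 columns, got {x.shape}")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class ICCResult:
    """Two-way intraclass correlation for the average of k raters."""

    form: str  # "2k" or "3k"
    estimate: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    ms_rows: float
    ms_cols: float
    ms_error: float


def icc(data: RatingMatrix | np.ndarray, form: str = "2k") -> ICCResult:
    """ICC(2,k) or ICC(3,k) of a complete targets x raters matrix.

    Two-way ANOVA decomposition (targets = rows, raters = columns):

    - ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n) — absolute agreement,
      raters treated as a random sample.
    - ICC(3,k) = (MSR - MSE) / MSR — consistency, raters fixed.

    The p-value comes from the F test of MSR/MSE with (n-1, (n-1)(k-1)) df.
    """
    form = form.lower().replace("(", "").replace(")", "").replace(",", "").replace("icc", "")
    if form not in ("2k", "3k"):
        raise InputError(f"form must be '2k' or '3k', got {form!r}")
    x = _as_matrix(data)
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"icc needs >= 2 targets and >= 2 raters, got {x.shape}")
    grand = x.mean()
    ss_rows = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if msr == 0:
        raise DegenerateDataError("zero between-target variance; ICC undefined")
    if form == "3k":
        estimate = (msr - mse) / msr
    else:
        estimate = (msr - mse) / (msr + (msc - mse) / n)
    if mse == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = msr / mse
        p = float(scipy.stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
    return ICCResult(
        form=form, estimate=float(estimate), f_statistic=float(f_stat),
        df1=n - 1, df2=(n - 1) * (k - 1), p_value=p,
        ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
    )


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_r(x, y) -> PearsonResult:
    """Sample Pearson correlation with a two-tailed p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise InputError(f"pearson_r needs n >= 3, got n = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input vector; correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z confidence interval for a correlation."""
    if n <= 3:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zcrit = scipy.stats.norm.ppf(0.5 + level / 2.0)
    return (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))


class PairedTResult(NamedTuple):
    t: float
    dof: int
    p: float
    ci: tuple[float, float]  # 95% CI of the mean difference x - y


def paired_t(x, y) -> PairedTResult:
    """Classical paired t-test, two-tailed, with 95% CI on the mean difference."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise InputError(f"paired_t needs n >= 2, got n = {x.size}")
    d = x - y
    if d.var(ddof=1) == 0:
        raise DegenerateDataError("zero variance of paired differences; t undefined")
    res = scipy.stats.ttest_rel(x, y)
    ci = res.confidence_interval(0.95)
    return PairedTResult(
        t=float(res.statistic), dof=int(x.size - 1), p=float(res.pvalue),
        ci=(float(ci.low), float(ci.high)),
    )


def mean_ci(x, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a sample mean."""
    x = np.asarray(x, dtype=np.float64)
    se = x.std(ddof=1) / np.sqrt(x.size)
    tcrit = scipy.stats.t.ppf(0.5 + level / 2.0, x.size - 1)
    return (float(x.mean() - tcrit * se), float(x.mean() + tcrit * se))


@dataclass
class RegressionResult:
    """Standardized multiple regression (beta weights)."""

    predictors: list[str]
    standardized_betas: np.ndarray
    t_statistics: np.ndarray
    dof: int
    p_values: np.ndarray
    confidence_intervals: np.ndarray  # (p, 2) 95% bounds on beta
    r_squared: float


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise DegenerateDataError("constant variable cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def standardized_ols(y, predictors, names: Sequence[str] | None = None) -> RegressionResult:
    """OLS on z-scored variables; coefficients are standardized betas.

    The model is fitted with an intercept (which is 0 by construction on
    standardized data and is not reported); t statistics use n - p - 1
    degrees of freedom and p-values are two-tailed, with 95% CIs on beta.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(predictors, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise InputError(f"y has shape {y.shape}, predictors have {n} rows")
    if n <= p + 1:
        raise InputError(f"need n > p + 1 observations, got n={n}, p={p}")
    names = list(names) if names is not None else [f"x{i + 1}" for i in range(p)]
    if len(names) != p:
        raise InputError(f"{len(names)} names for {p} predictors")
    zX = _zscore(X)
    zy = _zscore(y[:, None])[:, 0]
    if np.linalg.matrix_rank(zX) < p:
        corr = np.corrcoef(zX, rowvar=False)
        dep = [
            f"{names[i]}~{names[j]}"
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise CollinearityError(
            "rank-deficient design after standardization"
            + (f" (collinear: {', '.join(dep)})" if dep else f" among {names}")
        )
    fit = sm.OLS(zy, sm.add_constant(zX)).fit()
    ci = np.asarray(fit.conf_int(0.05))[1:]
    return RegressionResult(
        predictors=names,
        standardized_betas=np.asarray(fit.params[1:]),
        t_statistics=np.asarray(fit.tvalues[1:]),
        dof=int(fit.df_resid),
        p_values=np.asarray(fit.pvalues[1:]),
        confidence_intervals=ci,
        r_squared=float(fit.rsquared),
    )


def correlation_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-tailed p over a DataFrame's numeric columns."""
    num = table.select_dtypes("number")
    cols = list(num.columns)
    if len(cols) < 2:
        raise InputError("correlation matrix needs at least two numeric columns")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = pearson_r(num.iloc[:, i].to_numpy(), num.iloc[:, j].to_numpy())
            r[i, j] = r[j, i] = res.r
            p[i, j] = p[j, i] = res.p
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
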