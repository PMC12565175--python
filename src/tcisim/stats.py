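"""Statistical layer: proportion CIs, group comparisons and multivariable models.

Conventions follow the study's reporting: Wilson score intervals for
proportions, pooled-variance (Student) two-sample t tests, chi-square when
all expected cell counts reach 5 and Fisher's exact test otherwise, logistic
regression reported as odds ratios with Wald CIs, and linear regression with
R².  Regressions use urgency, age and BMI as predictors (BMI rather than
height and weight, to avoid collinearity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning


class DegenerateTestError(ValueError):
    """Raised when a test is undefined for the given data (e.g. n = 0, zero margin)."""


class SeparationError(RuntimeError):
    """Raised when logistic-regression estimates do not exist (perfect separation)."""


@dataclass(frozen=True)
class ProportionResult:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.proportion <= self.ci_high <= 1.0


@dataclass(frozen=True)
class TTestResult:
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    pooled_sd: float


@dataclass(frozen=True)
class TwoByTwoResult:
    p_value: float
    method: str  # "chi-square" or "fisher"
    statistic: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    """Coefficient table plus model-level fit.

    ``table`` has one row per predictor with columns estimate / ci_low /
    ci_high / p_value; for logistic models the estimate columns are on the
    odds-ratio scale.
    """

    model_type: str  # "logistic" or "linear"
    table: pd.DataFrame
    n: int
    r_squared: float | None = None


def wilson_ci(k: int, n: int, level: float = 0.95) -> ProportionResult:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise DegenerateTestError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    p = k / n
    # guard float dust at the binomial boundaries
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return ProportionResult(k=k, n=n, proportion=p, ci_low=lo, ci_high=hi, level=level)


def _summaries(x) -> tuple[int, float, float]:
    if isinstance(x, tuple) and len(x) == 3:
        n, mean, sd = x
        return int(n), float(mean), float(sd)
    arr = np.asarray(x, dtype=float)
    return len(arr), float(arr.mean()), float(arr.std(ddof=1))


def two_sample_t(x, y, level: float = 0.95) -> TTestResult:
    """Pooled-variance two-sample t test on raw samples or (n, mean, sd) summaries.

    The summary path and the raw-sample path agree exactly for samples with
    the given moments.  Returns the difference in means (x − y), its t-based
    CI and the two-sided p value.
    """
    n1, m1, s1 = _summaries(x)
    n2, m2, s2 = _summaries(y)
    if n1 < 2 or n2 < 2:
        raise DegenerateTestError("each group needs n >= 2")
    if s1 == 0 and s2 == 0:
        raise DegenerateTestError("both groups have zero variance")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = m1 - m2
    tcrit = ss.t.ppf(0.5 + level / 2, df)
    tstat = diff / se
    p = 2 * ss.t.sf(abs(tstat), df)
    return TTestResult(
        difference=diff,
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        p_value=float(p),
        df=df,
        pooled_sd=math.sqrt(sp2),
    )


def two_by_two_test(table) -> TwoByTwoResult:
    """Chi-square test when all expected counts are >= 5, else Fisher's exact.

    ``table`` is a 2x2 array of non-negative counts.  The chi-square variant
    is uncorrected (no continuity correction), matching common statistical
    software defaults.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise DegenerateTestError("2x2 table has an empty margin")
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if (expected >= 5).all():
        chi2, p, _, _ = ss.chi2_contingency(tab, correction=False)
        return TwoByTwoResult(p_value=float(p), method="chi-square", statistic=float(chi2))
    _, p = ss.fisher_exact(tab.astype(int), alternative="two-sided")
    return TwoByTwoResult(p_value=float(p), method="fisher", statistic=None)


def _design(data: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    for pred in predictors:
        col = data[pred]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            codes, uniques = pd.factorize(col, sort=True)
            if len(uniques) != 2:
                raise ValueError(f"categorical predictor {pred!r} must be binary")
            X[f"{pred}[{uniques[1]}]"] = codes.astype(float)
        else:
            X[pred] = col.astype(float)
    return sm.add_constant(X)


def logistic_fit(
    data: pd.DataFrame, outcome: str, predictors: list[str], level: float = 0.95
) -> RegressionResult:
    """Multivariable logistic regression, reported as odds ratios with Wald CIs.

    Binary categorical predictors are dummy-coded against their first sorted
    level.  Perfect separation is flagged (raises) instead of returning
    unstable estimates.
    """
    y = data[outcome].astype(float)
    if len(data) < 10:
        raise DegenerateTestError("logistic fit needs at least 10 cases")
    if y.nunique() < 2:
        raise DegenerateTestError("outcome must have both classes present")
    X = _design(data, predictors)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("error", PerfectSeparationWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as err:
            raise SeparationError("perfect separation: no ML estimates") from err
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge")
    ci = fit.conf_int(alpha=1 - level)
    table = pd.DataFrame(
        {
            "estimate": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    return RegressionResult(model_type="logistic", table=table, n=len(data))


def linear_fit(
    data: pd.DataFrame, outcome: str, predictors: list[str], level: float = 0.95
) -> RegressionResult:
    """Multivariable OLS with coefficient CIs and R²."""
    if len(data) <= len(predictors) + 1:
        raise DegenerateTestError("need n > number of predictors + 1")
    X = _design(data, predictors)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"columns: {list(X.columns)}"
        )
    fit = sm.OLS(data[outcome].astype(float), X).fit()
    ci = fit.conf_int(alpha=1 - level)
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": fit.pvalues,
        }
    ).drop(index="const")
    return RegressionResult(
        model_type="linear", table=table, n=len(data), r_squared=float(fit.rsquared)
    )
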