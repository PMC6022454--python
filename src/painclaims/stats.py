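"""Closed-form significance tests for proportions and correlations.

Three procedures: the pooled two-sample z test for a difference of
proportions, the one-sample z test for a proportion, and the t test for a
Pearson correlation coefficient (t = r sqrt(n-2) / sqrt(1-r^2), n-2 df).
All tests are two-sided; no continuity correction; no multiple-testing
adjustment (raw p-values are reported along with the number of tests
performed, see :func:`county_correlations`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .claims import ValidationError

__all__ = [
    "TestResult",
    "two_sample_z",
    "one_sample_z",
    "corr_t_test",
    "county_correlations",
    "COUNTY_COVARIATES",
]

COUNTY_COVARIATES = ("median_income", "pct_poverty", "pct_bachelors")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sided significance test."""

    statistic: float
    p_value: float
    n: int | tuple[int, int]
    estimate: float | tuple[float, float]
    sided: str = "two"
    test: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")

    def __repr__(self) -> str:  # compact, summary-table friendly
        return (f"TestResult({self.test or 'z'}: statistic={self.statistic:.4f}, "
                f"p={self.p_value:.4g}, n={self.n})")


def two_sample_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Pooled two-sample z test for the difference between proportions.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    two-sided p from the standard normal.  A degenerate pooled proportion
    (0 or 1) has no variance; the statistic is reported as 0 with a warning.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("both sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); z undefined, "
                      "reported as 0", RuntimeWarning, stacklevel=2)
        return TestResult(0.0, 1.0, (n1, n2), (p1, p2), test="two_sample_z")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), (n1, n2), (p1, p2), test="two_sample_z")


def one_sample_z(x: int, n: int, p0: float) -> TestResult:
    """One-sample z test of a proportion against the null value p0.

    z = (x/n - p0) / sqrt(p0 (1-p0) / n); two-sided p from the standard
    normal.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValidationError("x must satisfy 0 <= x <= n")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"null proportion must lie strictly in (0, 1), got {p0}")
    phat = x / n
    z = (phat - p0) / math.sqrt(p0 * (1.0 - p0) / n)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), n, phat, test="one_sample_z")


def corr_t_test(pairs) -> TestResult:
    """t test for a Pearson correlation coefficient.

    *pairs* is a sequence of (x, y) pairs, or a 2-column array.  Computes
    Pearson r, then t = r sqrt(n-2) / sqrt(1-r^2) referred to a
    t-distribution with n-2 degrees of freedom (two-sided).  |r| = 1 is
    degenerate: p is reported as 0 with a warning.
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be a sequence of (x, y) pairs")
    n = arr.shape[0]
    if n < 3:
        raise ValidationError("correlation test needs at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValidationError("constant series: correlation undefined")
    r = float(((x - x.mean()) * (y - y.mean())).sum() / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: exactly collinear data, p reported as 0",
                      RuntimeWarning, stacklevel=2)
        return TestResult(math.inf if r > 0 else -math.inf, 0.0, n, r,
                          test="corr_t")
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return TestResult(t, min(p, 1.0), n, r, test="corr_t")


def county_correlations(
    table: pd.DataFrame,
    outcome: str = "prevalence",
) -> pd.DataFrame:
    """Correlate a county-level outcome with the socioeconomic covariates.

    *table* has one row per county with the covariates ``median_income``,
    ``pct_poverty`` and ``pct_bachelors`` plus the outcome column
    (``prevalence_pct``, ``public_pct`` or ``private_pct`` according to
    *outcome* in {"prevalence", "public_share", "private_share"}).

    Correlations are computed on raw values, so "public-insurance share is
    positively associated with *lower* income" appears as a negative r
    between income and public share.  Returns one row per covariate with
    r, t, p and n, plus the total number of tests performed (no
    multiplicity adjustment is applied).
    """
    col = {"prevalence": "prevalence_pct", "public_share": "public_pct",
           "private_share": "private_pct"}.get(outcome)
    if col is None:
        raise ValueError(f"unknown outcome {outcome!r}")
    if col not in table.columns:
        raise ValidationError(f"outcome column {col!r} absent from table")
    if len(table) < 3:
        raise ValidationError("need at least 3 counties")
    if "county" in table.columns and table["county"].duplicated().any():
        raise ValidationError("one row per county required")
    for cov in COUNTY_COVARIATES:
        if cov not in table.columns:
            raise ValidationError(f"missing covariate column {cov!r}")
        missing = table[cov].isna()
        if missing.any():
            county = (table.loc[missing, "county"].iloc[0]
                      if "county" in table.columns else f"row {missing.idxmax()}")
            raise ValidationError(f"missing covariate {cov!r} for county {county}")

    rows = []
    for cov in COUNTY_COVARIATES:
        res = corr_t_test(np.column_stack([table[cov].to_numpy(float),
                                           table[col].to_numpy(float)]))
        rows.append({"outcome": outcome, "covariate": cov, "r": res.estimate,
                     "t": res.statistic, "p_value": res.p_value, "n": res.n,
                     "n_tests": len(COUNTY_COVARIATES)})
    return pd.DataFrame(rows)
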