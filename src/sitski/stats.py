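"""Statistical layer: validation tables, descriptives, correlations, agreement.

Conventions
-----------
Reported standard deviations default to the *population* form (divide by
``n``), matching the convention of measurement-accuracy tables in the
sports-video literature; the sample form (``n - 1``) is available by
flag.  Confidence intervals always use the sample-SD estimator with the
Student t quantile, ``mean +/- t(0.975, n-1) * sd / sqrt(n)``.

The agreement ICC is the two-way, absolute-agreement, single-measure
form ICC(A,1) (McGraw & Wong), the standard for method-comparison
studies.  All p-values are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ValidationRecord",
    "DescriptiveSummary",
    "UndefinedCorrelation",
    "validation_table",
    "describe",
    "ci_from_moments",
    "correlate",
    "agreement_tests",
    "icc_single_absolute",
    "one_sample_t",
    "normality_check",
    "PATTERN_CODES",
]

#: ordinal codes of the closest-approach pattern classes for rank correlations
PATTERN_CODES = {"before": -1, "at": 0, "after": 1}


class UndefinedCorrelation(ValueError):
    """A correlation coefficient is undefined (zero variance in an input)."""


@dataclass(frozen=True)
class ValidationRecord:
    """One measured-vs-analyzed distance pair with derived errors."""

    trial_id: int
    measured: float
    analyzed: float
    error: float
    rel_error: float


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    min: float
    max: float
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float


def _sd(values: np.ndarray, mode: str) -> float:
    if mode == "population":
        return float(values.std(ddof=0))
    if mode == "sample":
        return float(values.std(ddof=1))
    raise ValueError(f"sd_mode must be 'population' or 'sample', got {mode!r}")


def validation_table(
    measured, analyzed, sd_mode: str = "population"
) -> tuple[list[ValidationRecord], pd.DataFrame]:
    """Per-trial absolute/relative errors plus a mean/SD summary row.

    Returns the per-trial records and a two-row DataFrame (``mean``,
    ``sd``) over the measured, analyzed, error and relative-error
    columns.
    """
    m = np.asarray(measured, dtype=float)
    a = np.asarray(analyzed, dtype=float)
    if m.shape != a.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("measured and analyzed must be equal-length 1-D, n >= 2")
    if np.any(m <= 0):
        raise ValueError("measured distances must be positive")
    err = np.abs(a - m)
    rel = 100.0 * err / m
    records = [
        ValidationRecord(i + 1, float(m[i]), float(a[i]), float(err[i]), float(rel[i]))
        for i in range(m.size)
    ]
    cols = {"measured_m": m, "analyzed_m": a, "error_m": err, "rel_error_pct": rel}
    summary = pd.DataFrame(
        {k: [v.mean(), _sd(v, sd_mode)] for k, v in cols.items()}, index=["mean", "sd"]
    )
    return records, summary


def ci_from_moments(mean: float, sd_sample: float, n: int) -> tuple[float, float]:
    """t-based 95% CI of the mean from summary moments (sample-SD input)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    half = _sps.t.ppf(0.975, n - 1) * sd_sample / math.sqrt(n)
    return mean - half, mean + half


def describe(values, sd_mode: str = "population") -> DescriptiveSummary:
    """Min/max/mean/SD and the t-based 95% CI of the mean.

    The reported SD follows ``sd_mode``; the CI always uses the sample
    estimator.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("describe needs a 1-D vector with n >= 2")
    lo, hi = ci_from_moments(float(v.mean()), float(v.std(ddof=1)), v.size)
    return DescriptiveSummary(
        n=int(v.size),
        min=float(v.min()),
        max=float(v.max()),
        mean=float(v.mean()),
        sd=_sd(v, sd_mode),
        ci95_low=lo,
        ci95_high=hi,
    )


def correlate(xs, ys, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value.

    Pearson is for continuous variables; Spearman for ordinal ones (use
    :data:`PATTERN_CODES` to code the closest-approach pattern classes).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation("an input has zero variance")
    if method == "pearson":
        r = _sps.pearsonr(x, y)
    elif method == "spearman":
        r = _sps.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r.statistic), float(r.pvalue)


def icc_single_absolute(a, b) -> float:
    """ICC(A,1): two-way, absolute-agreement, single-measure ICC of two raters.

    Computed from the two-way ANOVA mean squares (rows = subjects,
    columns = raters)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    Degenerate all-equal input returns 1.0.
    """
    x = np.column_stack([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0.0:
        return 1.0
    return (msr - mse) / denom


def agreement_tests(a, b) -> dict:
    """Paired-sample t-test and ICC(A,1) between two paired series."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length 1-D vectors with n >= 3")
    if np.allclose(x, y):
        paired = (0.0, 1.0)
    else:
        res = _sps.ttest_rel(x, y)
        paired = (float(res.statistic), float(res.pvalue))
    return {"paired_t": paired, "icc": icc_single_absolute(x, y)}


def one_sample_t(values, reference: float) -> tuple[float, float]:
    """Classical one-sample t-test against a reference constant.

    Zero-variance input with mean off the reference yields an infinite
    statistic (p = 0); zero-variance on the reference yields (0, 1).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector with n >= 2")
    if v.std(ddof=1) == 0.0:
        if v.mean() == reference:
            return 0.0, 1.0
        return math.copysign(math.inf, v.mean() - reference), 0.0
    res = _sps.ttest_1samp(v, reference)
    return float(res.statistic), float(res.pvalue)


def normality_check(values) -> tuple[float, float]:
    """Advisory Shapiro-Wilk normality test: (W, p)."""
    v = np.asarray(values, dtype=float)
    res = _sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)
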