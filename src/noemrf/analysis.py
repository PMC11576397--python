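"""ROI statistics and evaluation metrics for quantitative parameter maps.

Covers the standard validation toolkit for fingerprinting reconstructions:
per-ROI summary statistics (mean, sample s.d., boxplot quartiles with
1.5 x IQR whiskers), Pearson correlation against ground truth, normalized
RMSE, and the two-tailed paired t-test used for WM-vs-GM comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RoiSummary", "roi_summary", "pearson_r", "nrmse", "paired_ttest"]

#: Conventional significance threshold for WM/GM group comparisons.
SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class RoiSummary:
    """Summary statistics of one parameter within one ROI."""

    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    n_pixels: int


def roi_summary(values_map: np.ndarray, roi_mask: np.ndarray) -> RoiSummary:
    """Sample statistics over the masked pixels, ignoring missing (NaN)
    values; s.d. uses the n-1 denominator; whiskers are quartile -/+
    1.5 x IQR."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    vals = np.asarray(values_map, dtype=float)[roi_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI is empty after removing missing values")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    return RoiSummary(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(q1 - 1.5 * iqr),
        whisker_high=float(q3 + 1.5 * iqr),
        n_pixels=int(vals.size),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r is undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def nrmse(estimated, truth, normalization: str = "range") -> float:
    """Root-mean-square error normalized by the truth's range (default),
    mean, or max."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimated and truth must have equal shape")
    rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
    if normalization == "range":
        scale = float(np.ptp(tru))
    elif normalization == "mean":
        scale = float(np.mean(tru))
    elif normalization == "max":
        scale = float(np.max(np.abs(tru)))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if scale <= 0:
        raise ValueError(f"truth {normalization} must be positive")
    return rmse / scale


def paired_ttest(group_a, group_b) -> tuple[float, float]:
    """Two-tailed paired t-test on n-1 degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("groups must be 1-D of equal length")
    if a.size < 2:
        raise ValueError("paired_ttest requires n >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.all(d == d[0]):
        raise ValueError(
            "zero-variance nonzero differences: the t statistic is unbounded"
        )
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
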