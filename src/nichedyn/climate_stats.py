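"""Statistical comparisons of climatic conditions between two taxa.

Mean predictor values at occurrences are compared with Welch's
independent-samples t-test; per-predictor ranges (max − min of the
min–max-scaled values) are compared with a paired-samples t-test across
the predictor set; the overall "times wider" factor is the ratio of mean
scaled ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .predictors import SampleMatrix


@dataclass
class TTestResult:
    statistic: float
    df: float
    p: float
    mean_diff: float
    n1: int
    n2: int


def independent_t(values_a: np.ndarray, values_b: np.ndarray, welch: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (Welch by default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both samples with equal means; t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_diff=float(a.mean() - b.mean()),
        n1=a.size,
        n2=b.size,
    )


def paired_t(ranges_a: np.ndarray, ranges_b: np.ndarray) -> TTestResult:
    """Two-sided paired-samples t-test on per-predictor range pairs."""
    a = np.asarray(ranges_a, dtype=float)
    b = np.asarray(ranges_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0) and np.allclose(d.mean(), 0):
        raise ValueError("all paired differences are zero; t undefined")
    res = stats.ttest_rel(a, b)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(a.size - 1),
        p=float(res.pvalue),
        mean_diff=float(d.mean()),
        n1=a.size,
        n2=b.size,
    )


def column_ranges(matrix: SampleMatrix) -> np.ndarray:
    """Per-column range (max − min) of a sample matrix."""
    x = matrix.to_numpy()
    return x.max(axis=0) - x.min(axis=0)


def range_breadth_ratio(
    scaled_a: SampleMatrix, scaled_b: SampleMatrix, aggregate: str = "ratio_of_means"
) -> float:
    """How many times wider group a's climatic ranges are than group b's.

    Both matrices must be scaled against a common reference. The default
    aggregation is mean(range_a) / mean(range_b); ``"mean_of_ratios"``
    averages the per-predictor ratios instead (columns with zero range in b
    are skipped there).
    """
    if list(scaled_a.columns) != list(scaled_b.columns):
        raise ValueError("matrices must share the same predictor columns")
    ra = column_ranges(scaled_a)
    rb = column_ranges(scaled_b)
    if aggregate == "ratio_of_means":
        if rb.mean() == 0:
            raise ZeroDivisionError("denominator group has zero mean range")
        return float(ra.mean() / rb.mean())
    if aggregate == "mean_of_ratios":
        ok = rb > 0
        if not ok.any():
            raise ZeroDivisionError("denominator group has zero range in every predictor")
        return float(np.mean(ra[ok] / rb[ok]))
    raise ValueError("aggregate must be 'ratio_of_means' or 'mean_of_ratios'")
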