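"""Descriptive cohort statistics and two-sample t-test comparisons.

Each metric is summarised per cohort (n, mean, sample SD, min, max) and
compared between cohorts with a two-sided two-sample t-test in both the
pooled-variance (equal variances) and Welch (unequal variances)
variants, flagged at the 0.05 and 0.01 significance levels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError


@dataclass(frozen=True)
class CohortSummary:
    metric: str
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class ComparisonReport:
    metric: str
    pooled: TTestResult
    welch: TTestResult

    @property
    def significant_at_0p05(self) -> bool:
        return self.pooled.p < 0.05 and self.welch.p < 0.05

    @property
    def significant_at_0p01(self) -> bool:
        return self.pooled.p < 0.01 and self.welch.p < 0.01


def summarize_cohort(values: Sequence[float], metric: str = "") -> CohortSummary:
    """n, mean, sample SD (n−1), min, max of one metric."""
    arr = np.asarray([v for v in values if v is not None and math.isfinite(v)],
                     dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"metric {metric!r}: need >= 2 finite values, got {arr.size}")
    return CohortSummary(metric=metric, n=int(arr.size), mean=float(arr.mean()),
                         sd=float(arr.std(ddof=1)), min=float(arr.min()),
                         max=float(arr.max()))


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     equal_variance: bool = True) -> TTestResult:
    """Two-sided two-sample t-test.

    Pooled variance with df = na+nb−2 when ``equal_variance``; Welch with
    Welch–Satterthwaite df otherwise.  When both samples have zero
    variance and equal means the statistic is taken as t = 0, p = 1 by
    convention (the samples are indistinguishable) rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        df = a.size + b.size - 2.0
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, a.mean() - b.mean()),
                           df=df, p=0.0)
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def compare_cohorts(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                    metric_names: Sequence[str]) -> list[ComparisonReport]:
    """Per-metric pooled and Welch comparisons between two metric tables."""
    reports = []
    for name in metric_names:
        for table, tag in ((metrics_a, "first"), (metrics_b, "second")):
            if name not in table.columns:
                raise InvalidArgumentError(f"metric {name!r} missing from {tag} table")
        a = metrics_a[name].dropna().to_numpy(dtype=float)
        b = metrics_b[name].dropna().to_numpy(dtype=float)
        reports.append(ComparisonReport(
            metric=name,
            pooled=two_sample_ttest(a, b, equal_variance=True),
            welch=two_sample_ttest(a, b, equal_variance=False),
        ))
    return reports
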