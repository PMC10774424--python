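"""Nonparametric group comparisons and figure-level summaries.

Mirrors the statistics used throughout the study: two-sided Kolmogorov-
Smirnov for two-group comparisons, Kruskal-Wallis as the omnibus rank test,
and effect sizes reported with the two-sided Mann-Whitney test as absolute
differences of group medians, in the metric's native units.  No
multiple-testing correction is applied by default (raw p-values are
reported); Bonferroni is available behind a flag for users who want it.

Group summaries are median plus quartiles, with numpy's linear interpolation
convention for the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

TEST_NAMES = ("ks_two_sided", "kruskal_wallis", "mann_whitney")


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size_abs_median_diff: float
    group_sizes: tuple[int, ...]
    p_adjusted: float | None = None


@dataclass
class GroupSummary:
    median: float
    q25: float
    q75: float
    n: int


def compare_two_groups(
    a: Sequence[float], b: Sequence[float], test_name: str = "ks_two_sided"
) -> ComparisonResult:
    """Two-sample nonparametric comparison with a median-difference effect size.

    The effect size is |median(a) - median(b)| in the metric's own units,
    never the test statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if test_name == "ks_two_sided":
        res = stats.ks_2samp(a, b, alternative="two-sided")
    elif test_name == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test_name == "kruskal_wallis":
        res = stats.kruskal(a, b)
    else:
        raise ValueError(f"unknown test {test_name!r}; expected one of {TEST_NAMES}")
    return ComparisonResult(
        test_name=test_name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_abs_median_diff=float(abs(np.median(a) - np.median(b))),
        group_sizes=(len(a), len(b)),
    )


def compare_multi_groups(groups: Sequence[Sequence[float]]) -> ComparisonResult:
    """Kruskal-Wallis omnibus rank test across two or more groups.

    The effect size reported is the largest absolute pairwise difference of
    group medians.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs at least 2 samples")
    res = stats.kruskal(*arrs)
    medians = [float(np.median(g)) for g in arrs]
    effect = max(abs(m1 - m2) for m1 in medians for m2 in medians)
    return ComparisonResult(
        test_name="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size_abs_median_diff=effect,
        group_sizes=tuple(len(g) for g in arrs),
    )


def summarize_group(samples: Sequence[float]) -> GroupSummary:
    """Median and quartiles (linear-interpolation convention)."""
    s = np.asarray(samples, dtype=float)
    if len(s) < 1:
        raise ValueError("at least one sample is required")
    return GroupSummary(
        median=float(np.median(s)),
        q25=float(np.percentile(s, 25)),
        q75=float(np.percentile(s, 75)),
        n=len(s),
    )


def bonferroni(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Optional multiple-testing correction (off by default in reports)."""
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, r.p_value * m)
    return list(results)
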