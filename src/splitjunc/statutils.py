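"""Thin wrappers around scipy rank and t statistics with a uniform result type."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StatResult:
    """A named test statistic with its p-value and group sizes."""

    statistic: str
    value: float
    p_value: float
    n1: int
    n2: int
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        # nan is allowed: degenerate inputs (e.g. zero-variance differences)
        if not np.isnan(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def rank_sum_test(
    x, y, alternative: str = "two-sided", statistic_name: str = "W"
) -> StatResult:
    """Two-sample Wilcoxon rank-sum / Mann-Whitney U test.

    The statistic reported is the U of the first sample (identical to the W
    reported by R's ``wilcox.test``).  The exact null distribution is used
    for small tie-free samples (min(n) <= 10), the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return StatResult(statistic_name, float(res.statistic), float(res.pvalue),
                      len(x), len(y), alternative)


def paired_t_test(x, y, alternative: str = "two-sided") -> StatResult:
    """Paired t-test between matched samples x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired test needs >= 2 matched pairs")
    res = stats.ttest_rel(x, y, alternative=alternative)
    return StatResult("T", float(res.statistic), float(res.pvalue),
                      len(x), len(y), alternative)


def one_sample_t_test(diffs, popmean: float = 0.0,
                      alternative: str = "two-sided") -> StatResult:
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < 2:
        raise ValueError("need >= 2 observations")
    res = stats.ttest_1samp(diffs, popmean, alternative=alternative)
    return StatResult("T", float(res.statistic), float(res.pvalue),
                      len(diffs), 0, alternative)
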