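"""Inferential layer over similarity profiles: t-tests and their 9x9 tables.

Classical paired and independent two-sample t-tests (two-sided), applied to
the per-subject direction similarity profiles: for each group, all 36
direction pairs are compared with a paired t-test, giving a symmetric 9x9
p-value matrix (diagonal 1). Raw p-values are reported; a Bonferroni column
is available on request.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sci_stats


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    flag: Optional[str] = None


def paired_t(x, y) -> TestResult:
    """Paired two-sided t-test on per-subject differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired samples must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise StatsError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(statistic=0.0, p_value=1.0, df=n - 1,
                              flag="all differences zero")
        raise StatsError("differences are a nonzero constant; t statistic undefined")
    t, p = sci_stats.ttest_rel(x, y)
    return TestResult(statistic=float(t), p_value=float(p), df=n - 1)


def independent_t(x, y, equal_var: bool = True) -> TestResult:
    """Independent two-sided t-test (Student by default, Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise StatsError("each sample must be 1-D with at least 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return TestResult(statistic=0.0, p_value=1.0,
                              df=x.size + y.size - 2, flag="both samples constant and equal")
        raise StatsError("both samples constant but unequal; t statistic infinite")
    t, p = sci_stats.ttest_ind(x, y, equal_var=equal_var)
    df = x.size + y.size - 2 if equal_var else np.nan
    return TestResult(statistic=float(t), p_value=float(p), df=df)


@dataclass
class PairwiseTestMatrix:
    p_values: np.ndarray                # 9x9, symmetric, diagonal 1
    statistics: np.ndarray
    test: str
    group: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        labels = [f"target_{t}" for t in range(1, 10)]
        return pd.DataFrame(self.p_values, index=labels, columns=labels)


def pairwise_direction_tests(profiles: pd.DataFrame, group: Optional[str] = None,
                             bonferroni: bool = False) -> PairwiseTestMatrix:
    """Paired t-tests between all 36 direction pairs of similarity profiles.

    ``profiles`` is subjects x 9 (complete rows only are used). With
    ``bonferroni=True`` p-values are multiplied by 36 and capped at 1.
    """
    values = profiles.dropna().to_numpy(dtype=float)
    if values.shape[1] != 9:
        raise StatsError("profiles must have 9 direction columns")
    if values.shape[0] < 2:
        raise StatsError("need at least 2 complete subjects")
    p = np.ones((9, 9))
    t = np.zeros((9, 9))
    n_tests = 36
    for a in range(9):
        for b in range(a + 1, 9):
            res = paired_t(values[:, a], values[:, b])
            p_ab = min(1.0, res.p_value * n_tests) if bonferroni else res.p_value
            p[a, b] = p[b, a] = p_ab
            t[a, b] = res.statistic
            t[b, a] = -res.statistic
    return PairwiseTestMatrix(p_values=p, statistics=t,
                              test="paired_t" + ("_bonferroni" if bonferroni else ""),
                              group=group)


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Pearson r and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need equal-length samples of at least 3 values")
    r, p = sci_stats.pearsonr(x, y)
    return float(r), float(p)
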