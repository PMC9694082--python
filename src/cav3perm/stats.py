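"""Group statistics: mean +/- SEM, Student's t, one-way ANOVA, Tukey HSD.

Sums of squares and the studentized-range q statistics are computed here;
tail probabilities come from scipy's F and studentized-range distributions
(the latter is evaluated by numerical quadrature to well below the 1e-4
accuracy this module promises for adjusted p values).  Unequal group sizes
use the Tukey-Kramer form.  Significance is reported at the fixed 0.05
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "mean_sem",
    "one_way_anova",
    "tukey_hsd",
    "t_test_two_sample",
]

ALPHA = 0.05


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]
    grand_mean: float
    ss_between: float
    ss_within: float
    ms_within: float


@dataclass
class TukeyPair:
    group_i: int
    group_j: int
    mean_diff: float
    q_stat: float
    p_adj: float
    significant: bool


@dataclass
class TukeyResult:
    pairs: list[TukeyPair]
    alpha: float = ALPHA


def mean_sem(values) -> tuple[float, float, int]:
    """(mean, SEM, n) with the n-1 sample standard deviation.

    SEM needs at least two values.
    """
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("SEM is undefined for fewer than 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(n)), int(n)


def _validate_groups(groups) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for idx, g in enumerate(arrs):
        if g.size == 0:
            raise ValueError(f"group {idx} is empty")
        if g.size < 2:
            raise ValueError(f"group {idx} has fewer than 2 values")
    return arrs


def one_way_anova(groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA from between/within sums of squares."""
    arrs = _validate_groups(groups)
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    n_total = int(ns.sum())
    means = np.array([g.mean() for g in arrs])
    grand = float(np.concatenate(arrs).mean())

    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - g.mean()) ** 2) for g in arrs))
    df_b, df_w = k - 1, n_total - k
    if ssw <= 0:
        raise ValueError("zero within-group variance; F is undefined")
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means=[float(m) for m in means],
        grand_mean=grand,
        ss_between=ssb,
        ss_within=ssw,
        ms_within=msw,
    )


def tukey_hsd(groups, alpha: float = ALPHA) -> TukeyResult:
    """All-pairs Tukey(-Kramer) HSD after a one-way ANOVA.

    q = |mean_i - mean_j| / sqrt(MS_within (1/n_i + 1/n_j) / 2); the
    adjusted p is the studentized-range upper tail with (k, N-k) parameters.
    """
    anova = one_way_anova(groups)
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[j].mean() - arrs[i].mean())
            se = math.sqrt(anova.ms_within * (1.0 / arrs[i].size + 1.0 / arrs[j].size) / 2.0)
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
            p_adj = min(max(p_adj, 0.0), 1.0)
            pairs.append(
                TukeyPair(
                    group_i=i,
                    group_j=j,
                    mean_diff=diff,
                    q_stat=float(q),
                    p_adj=p_adj,
                    significant=p_adj < alpha,
                )
            )
    return TukeyResult(pairs=pairs, alpha=alpha)


def t_test_two_sample(a, b, equal_variance: bool = True) -> tuple[float, float, float]:
    """Two-sample t test: (t, df, p); pooled variance by default, Welch optional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("degenerate zero-variance samples with equal means")
    res = sps.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(res.df), float(res.pvalue)
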