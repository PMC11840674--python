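"""Nonparametric group comparisons for cohort-level DRTC metrics.

Thin, uniformly-shaped wrappers over the vetted scipy routines:
Mann-Whitney U for independent groups, Wilcoxon signed-rank for paired
pre/post measurements, Kruskal-Wallis for more than two groups and
Fisher's exact test for 2×2 categorical tables. Every comparison returns a
:class:`GroupComparison` carrying the statistic, the two-sided p-value and
per-group medians with ranges (the cohort's reporting convention).

Exactness policy: the exact null distribution is used for the rank tests
at desk scale (combined n ≤ 20 without ties for Mann-Whitney, n ≤ 15
non-zero differences without ties for the signed-rank), the tie-corrected
normal approximation otherwise. Zero differences in the signed-rank test
are dropped (Wilcoxon's original rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "kruskal_wallis",
    "EXACT_MWU_MAX_N",
    "EXACT_WILCOXON_MAX_N",
]

EXACT_MWU_MAX_N = 20  # combined size for the exact Mann-Whitney path
EXACT_WILCOXON_MAX_N = 15  # non-zero pairs for the exact signed-rank path


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    test: str
    group_labels: tuple
    group_sizes: tuple
    statistic: float
    p_value: float
    medians: tuple
    ranges: tuple  # per group: (min, max)
    degenerate: bool = False
    note: str = ""


def _median_range(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(values)), (float(values.min()), float(values.max()))


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney_u(
    x, y, *, metric: str = "", labels: tuple = ("a", "b")
) -> GroupComparison:
    """Two-sided Mann-Whitney U test for two independent groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size) <= EXACT_MWU_MAX_N and not _has_ties(pooled)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    mx, rx = _median_range(x)
    my, ry = _median_range(y)
    return GroupComparison(
        metric=metric,
        test="mann_whitney",
        group_labels=tuple(labels),
        group_sizes=(x.size, y.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        medians=(mx, my),
        ranges=(rx, ry),
        note="exact" if exact else "asymptotic",
    )


def wilcoxon_signed_rank(
    pre, post, *, metric: str = "", labels: tuple = ("pre", "post")
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test for paired measurements.

    Zero differences are dropped before ranking; if every difference is
    zero the result is flagged degenerate with p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("paired vectors must have equal length")
    if pre.size == 0:
        raise ValueError("paired vectors must be non-empty")
    diff = post - pre
    nonzero = diff[diff != 0]
    m_pre, r_pre = _median_range(pre)
    m_post, r_post = _median_range(post)
    if nonzero.size == 0:
        return GroupComparison(
            metric=metric,
            test="wilcoxon_signed_rank",
            group_labels=tuple(labels),
            group_sizes=(pre.size, post.size),
            statistic=float("nan"),
            p_value=1.0,
            medians=(m_pre, m_post),
            ranges=(r_pre, r_post),
            degenerate=True,
            note="all differences zero",
        )
    exact = nonzero.size <= EXACT_WILCOXON_MAX_N and not _has_ties(np.abs(nonzero))
    res = sps.wilcoxon(
        pre,
        post,
        zero_method="wilcox",
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return GroupComparison(
        metric=metric,
        test="wilcoxon_signed_rank",
        group_labels=tuple(labels),
        group_sizes=(pre.size, post.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        medians=(m_pre, m_post),
        ranges=(r_pre, r_post),
        note="exact" if exact else "approx",
    )


def fisher_exact_2x2(table, *, metric: str = "", labels: tuple = ("a", "b")) -> GroupComparison:
    """Two-sided Fisher's exact test (minimum-likelihood summation).

    A table with a zero margin carries no information about association:
    it is flagged degenerate and p = 1 is reported.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    degenerate = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate:
        odds, p = float("nan"), 1.0
    else:
        odds, p = sps.fisher_exact(t, alternative="two-sided")
    sizes = tuple(int(v) for v in t.sum(axis=1))
    return GroupComparison(
        metric=metric,
        test="fisher_exact",
        group_labels=tuple(labels),
        group_sizes=sizes,
        statistic=float(odds),
        p_value=float(p),
        medians=(float("nan"), float("nan")),
        ranges=((float("nan"),) * 2, (float("nan"),) * 2),
        degenerate=bool(degenerate),
        note="zero margin" if degenerate else "",
    )


def kruskal_wallis(groups, *, metric: str = "", labels: tuple = ()) -> GroupComparison:
    """Kruskal-Wallis H test (tie-corrected) across ≥ 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        # identical constant data: H = 0 by convention, p = 1
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    med_rng = [_median_range(a) for a in arrays]
    if not labels:
        labels = tuple(f"group{i+1}" for i in range(len(arrays)))
    return GroupComparison(
        metric=metric,
        test="kruskal_wallis",
        group_labels=tuple(labels),
        group_sizes=tuple(a.size for a in arrays),
        statistic=float(stat),
        p_value=float(p),
        medians=tuple(m for m, _ in med_rng),
        ranges=tuple(r for _, r in med_rng),
    )
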