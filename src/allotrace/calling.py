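"""Differential-abundance definition of donor-reactive T-cell clones (DRTC).

A clone's template counts in two samples are compared with an exact
two-sided binomial test under a repertoire-size-weighted null: with
``n = count_a + count_b`` trials, the null success probability is
``p0 = total_a / (total_a + total_b)``, i.e. the templates of the clone are
assumed to distribute between the samples in proportion to the samples'
productive repertoire sizes. DRTC are the clones that, in the MLR-sorted
(proliferated) population versus the unstimulated pre-transplant PBMC,

1. have a combined count of at least ``count_floor`` (default 5),
2. reach Benjamini-Hochberg adjusted ``q < alpha`` (default 0.01), and
3. are at least ``fold_min``-fold (default 2) more frequent in the MLR sort.

Clones significant in the opposite direction are labelled
``enriched_unstim`` (they proliferate less than expected and are likely not
alloreactive); everything else is ``not_significant`` or
``below_count_floor``. The BH multiplicity counts only the clones tested in
this single pairwise comparison — analyses are per subject, never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io import DegenerateSampleError, RepertoireSample

__all__ = [
    "binomial_two_sided_p",
    "bh_adjust",
    "call_drtc",
    "classify_scatter",
    "DiffAbundanceResult",
    "DRTCSet",
    "CALL_CLASSES",
]

CALL_CLASSES = ("drtc", "enriched_unstim", "not_significant", "below_count_floor")

#: Relative tolerance used when comparing point probabilities in the
#: minimum-likelihood two-sided p-value; outcomes with probability up to
#: (1 + REL_TOL) times the observed one are counted into the p-value.
REL_TOL = 1e-7


def binomial_two_sided_p(
    count_a: int,
    count_b: int,
    total_a: int,
    total_b: int,
    *,
    method: str = "minlike",
    rel_tol: float = REL_TOL,
) -> float:
    """Exact two-sided binomial p-value under the repertoire-size null.

    ``method='minlike'`` (default) sums P(k | n, p0) over every outcome k
    whose point probability does not exceed that of the observed count (a
    relative tie tolerance ``rel_tol`` guards against floating-point
    near-ties). ``method='doubling'`` doubles the smaller tail instead.
    Both are symmetric under swapping the two samples.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a > total_a or count_b > total_b:
        raise ValueError("count exceeds its sample total")
    n = count_a + count_b
    if n == 0:
        raise ValueError("combined count is zero: no trials to test")
    p0 = total_a / (total_a + total_b)
    if method == "minlike":
        return float(_minlike_pvalues(np.array([count_a]), n, p0, rel_tol)[0])
    if method == "doubling":
        lower = binom.cdf(count_a, n, p0)
        upper = binom.sf(count_a - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown two-sided method {method!r}")


def _minlike_pvalues(ks: np.ndarray, n: int, p0: float, rel_tol: float = REL_TOL) -> np.ndarray:
    """Minimum-likelihood two-sided p-values for many observed counts at one n.

    Computes the full pmf once, sorts it, and answers each query by binary
    search on the sorted cumulative mass — O(n log n) total for any number
    of queries sharing the same (n, p0).
    """
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    thresholds = pmf[ks] * (1.0 + rel_tol)
    idx = np.searchsorted(sorted_pmf, thresholds, side="right")
    out = cum[np.clip(idx - 1, 0, n)]
    out[idx == 0] = 0.0  # cannot occur for an observed k, kept for safety
    return np.minimum(out, 1.0)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    With p-values sorted ascending, ``q_i = min_{j >= i} (p_j * m / j)``
    capped at 1. The adjusted values are monotone non-decreasing in p and
    never smaller than the raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class DiffAbundanceResult:
    """Per-clone record of the pairwise differential-abundance test."""

    clone: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    freq_a: float
    freq_b: float
    fold: float
    p_value: float
    q_value: float
    call: str


@dataclass
class DRTCSet:
    """The clones called donor-reactive for one subject and T-cell subset.

    ``results`` holds the full pairwise comparison table (all call classes);
    ``members`` is exactly the set of clone keys with ``call == 'drtc'``.
    Calling parameters are recorded for provenance.
    """

    subject_id: str
    subset: str
    results: pd.DataFrame
    parameters: dict = field(default_factory=dict)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.results.index[self.results["call"] == "drtc"])

    @property
    def member_results(self) -> pd.DataFrame:
        return self.results[self.results["call"] == "drtc"]

    def __len__(self) -> int:
        return len(self.members)

    def record(self, clone: str) -> DiffAbundanceResult:
        row = self.results.loc[clone]
        return DiffAbundanceResult(
            clone=clone,
            count_a=int(row["count_a"]),
            count_b=int(row["count_b"]),
            total_a=int(row["total_a"]),
            total_b=int(row["total_b"]),
            freq_a=float(row["freq_a"]),
            freq_b=float(row["freq_b"]),
            fold=float(row["fold"]),
            p_value=float(row["p_value"]),
            q_value=float(row["q_value"]),
            call=str(row["call"]),
        )


def call_drtc(
    mlr_sample: RepertoireSample,
    unstim_sample: RepertoireSample,
    *,
    alpha: float = 0.01,
    fold_min: float = 2.0,
    count_floor: int = 5,
    method: str = "minlike",
) -> DRTCSet:
    """Call donor-reactive clones from an MLR sort / unstimulated-PBMC pair.

    The clone universe is the union of productive clone keys across the two
    samples (count 0 where absent). Clones below the combined-count floor
    are never assigned a p-value and do not enter the BH multiplicity. A
    clone absent from the unstimulated sample (``freq_b == 0``) satisfies
    the fold criterion by convention — no pseudocount is added, so newly
    detected MLR clones can be called DRTC.

    Returns a :class:`DRTCSet` whose ``results`` index is the clone key with
    columns ``count_a, count_b, total_a, total_b, freq_a, freq_b, fold,
    p_value, q_value, call``. Side a is the MLR sort, side b the
    unstimulated sample.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    if fold_min <= 0:
        raise ValueError("fold_min must be positive")
    if count_floor < 1:
        raise ValueError("count_floor must be >= 1")

    counts_a = mlr_sample.counts
    counts_b = unstim_sample.counts
    total_a = mlr_sample.total_templates
    total_b = unstim_sample.total_templates
    if total_a <= 0 or total_b <= 0:
        raise DegenerateSampleError("both samples must carry productive templates")

    universe = counts_a.index.union(counts_b.index, sort=False)
    ca = counts_a.reindex(universe, fill_value=0).to_numpy(dtype=np.int64)
    cb = counts_b.reindex(universe, fill_value=0).to_numpy(dtype=np.int64)
    fa = ca / total_a
    fb = cb / total_b
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(fb > 0, fa / fb, np.where(fa > 0, np.inf, np.nan))

    combined = ca + cb
    tested = combined >= count_floor
    p = np.full(universe.size, np.nan)
    p0 = total_a / (total_a + total_b)
    if tested.any():
        ns = combined[tested]
        ks = ca[tested]
        pv = np.empty(ns.size)
        for n in np.unique(ns):
            sel = ns == n
            pv[sel] = _minlike_pvalues(ks[sel], int(n), p0) if method == "minlike" else [
                binomial_two_sided_p(int(k), int(n - k), total_a, total_b, method=method)
                for k in ks[sel]
            ]
        p[tested] = pv

    q = np.full(universe.size, np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    # fold gates with the zero-frequency convention
    gate_a = np.where(fb > 0, fa >= fold_min * fb, fa > 0)
    gate_b = np.where(fa > 0, fb >= fold_min * fa, fb > 0)
    significant = tested & (q < alpha)
    call = np.full(universe.size, "not_significant", dtype=object)
    call[~tested] = "below_count_floor"
    call[significant & gate_a] = "drtc"
    call[significant & gate_b & (call != "drtc")] = "enriched_unstim"

    results = pd.DataFrame(
        {
            "count_a": ca,
            "count_b": cb,
            "total_a": total_a,
            "total_b": total_b,
            "freq_a": fa,
            "freq_b": fb,
            "fold": fold,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=pd.Index(universe, name="rearrangement"),
    )
    return DRTCSet(
        subject_id=mlr_sample.subject_id or unstim_sample.subject_id,
        subset=mlr_sample.subset,
        results=results,
        parameters={
            "alpha": alpha,
            "fold_min": fold_min,
            "count_floor": count_floor,
            "method": method,
            "mlr_sample": mlr_sample.sample_id,
            "unstim_sample": unstim_sample.sample_id,
        },
    )


def classify_scatter(results: pd.DataFrame) -> dict[str, int]:
    """Count clones per call class; classes partition the clone universe.

    Mirrors the MLR-vs-unstimulated scatter: ``drtc`` (significantly and
    fold-wise more abundant in the MLR sort), ``enriched_unstim``
    (significantly more abundant in the unstimulated sample),
    ``not_significant`` and ``below_count_floor``.
    """
    counts = {c: 0 for c in CALL_CLASSES}
    if len(results):
        vc = results["call"].value_counts()
        for c in CALL_CLASSES:
            counts[c] = int(vc.get(c, 0))
    return counts
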