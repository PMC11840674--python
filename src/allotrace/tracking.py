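"""Longitudinal tracking of donor-reactive clones across compartments.

Once a subject's DRTC are defined in the pre-transplant MLR, their presence
and frequency are serially monitored in prospectively collected blood,
allograft-biopsy and urine samples. Graft-infiltrating DRTC are further
categorized by where else they were ever detected:

* ``pre_only``     — in the pre-transplant PBMC but not the paired
  post-transplant PBMC;
* ``pre_and_post`` — in both blood samples;
* ``post_only``    — newly detected in the post-transplant blood;
* ``graft_only``   — in neither blood sample (circulating below the
  detection limit).

The cumulative "detected pre-transplant" share is ``pre_only +
pre_and_post``. When the paired post-transplant PBMC is missing the
partition degrades to {pre_only, graft_only, undetermined} with an explicit
flag — never imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TIMEPOINT_ORDER, RepertoireSample
from .metrics import DRTCMetrics, drtc_metrics

__all__ = [
    "TrackingTable",
    "GraftCloneCategories",
    "UrineOverlapReport",
    "build_tracking",
    "categorize_graft_clones",
    "urine_graft_overlap",
    "longitudinal_drtc_summary",
    "GRAFT_CATEGORIES",
]

GRAFT_CATEGORIES = ("pre_only", "pre_and_post", "post_only", "graft_only")


def _sample_order_key(s: RepertoireSample) -> tuple:
    return (TIMEPOINT_ORDER.get(s.timepoint, 99), s.compartment, s.sample_id)


def _present(sample: RepertoireSample, clones) -> pd.Series:
    counts = sample.counts.reindex(clones, fill_value=0)
    return counts >= 1


@dataclass
class TrackingTable:
    """Clone × sample grid of presence, template count and frequency.

    Rows are DRTC clone keys; columns are the subject's samples ordered by
    timepoint then compartment. Every cell is defined — absent clones are
    recorded as (False, 0, 0).
    """

    subject_id: str
    subset: str
    counts: pd.DataFrame
    frequencies: pd.DataFrame
    sample_meta: pd.DataFrame

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format table (clone, sample_id, present, count, frequency)."""
        long = (
            self.counts.stack()
            .rename("count")
            .to_frame()
            .join(self.frequencies.stack().rename("frequency"))
            .reset_index()
        )
        long.columns = ["clone", "sample_id", "count", "frequency"]
        long["present"] = long["count"] >= 1
        return long[["clone", "sample_id", "present", "count", "frequency"]]


def build_tracking(drtc, samples: list[RepertoireSample]) -> TrackingTable:
    """Build the complete clone × sample tracking grid for one DRTC set."""
    members = sorted(drtc.members)
    subject = drtc.subject_id
    for s in samples:
        if s.subject_id and subject and s.subject_id != subject:
            raise ValueError(
                f"sample {s.sample_id!r} belongs to subject {s.subject_id!r}, "
                f"not {subject!r}"
            )
    ordered = sorted(samples, key=_sample_order_key)
    idx = pd.Index(members, name="clone")
    counts = pd.DataFrame(index=idx)
    freqs = pd.DataFrame(index=idx)
    meta_rows = []
    for s in ordered:
        c = s.counts.reindex(idx, fill_value=0).astype(np.int64)
        counts[s.sample_id] = c
        total = s.total_templates
        freqs[s.sample_id] = c / total if total else 0.0
        meta_rows.append(
            {
                "sample_id": s.sample_id,
                "timepoint": s.timepoint,
                "compartment": s.compartment,
                "subset": s.subset,
                "total_templates": total,
            }
        )
    return TrackingTable(
        subject_id=subject,
        subset=drtc.subset,
        counts=counts,
        frequencies=freqs,
        sample_meta=pd.DataFrame(meta_rows),
    )


@dataclass
class GraftCloneCategories:
    """Exclusive four-way categorization of graft-infiltrating DRTC.

    ``shares`` is ``None`` when no DRTC were detected in the graft (the
    partition is undefined on an empty universe). ``three_way`` marks the
    degraded partition used when the post-transplant PBMC is missing, in
    which case clones not seen pre-transplant are ``undetermined``.
    """

    subject_id: str
    subset: str
    labels: pd.Series
    counts: dict = field(default_factory=dict)
    shares: dict | None = None
    cumulative_pre_share: float | None = None
    three_way: bool = False

    @property
    def n_graft_drtc(self) -> int:
        return int(len(self.labels))


def categorize_graft_clones(
    drtc,
    graft: RepertoireSample,
    pre_pbmc: RepertoireSample,
    post_pbmc: RepertoireSample | None = None,
) -> GraftCloneCategories:
    """Categorize graft-detected DRTC by their detection in the blood.

    The clone universe is the DRTC detected (>= 1 template) in the graft
    sample. Presence in the pre- and post-transplant PBMC assigns each
    clone one exclusive label; shares are reported over the universe and
    always sum to 1 when it is non-empty.
    """
    for s in (graft, pre_pbmc) + (() if post_pbmc is None else (post_pbmc,)):
        if s.subject_id and drtc.subject_id and s.subject_id != drtc.subject_id:
            raise ValueError(
                f"sample {s.sample_id!r} is not from subject {drtc.subject_id!r}"
            )
    members = sorted(drtc.members)
    in_graft = _present(graft, members)
    universe = [c for c in members if in_graft[c]]
    categories = GRAFT_CATEGORIES if post_pbmc is not None else (
        "pre_only",
        "graft_only",
        "undetermined",
    )
    if not universe:
        return GraftCloneCategories(
            subject_id=drtc.subject_id,
            subset=drtc.subset,
            labels=pd.Series(dtype=object, name="category"),
            counts={c: 0 for c in categories},
            shares=None,
            cumulative_pre_share=None,
            three_way=post_pbmc is None,
        )

    pre = _present(pre_pbmc, universe)
    if post_pbmc is not None:
        post = _present(post_pbmc, universe)
        labels = pd.Series(
            np.select(
                [pre & post, pre & ~post, ~pre & post],
                ["pre_and_post", "pre_only", "post_only"],
                default="graft_only",
            ),
            index=pd.Index(universe, name="clone"),
            name="category",
        )
        counts = {c: int((labels == c).sum()) for c in GRAFT_CATEGORIES}
        n = len(universe)
        shares = {c: counts[c] / n for c in GRAFT_CATEGORIES}
        cum_pre = shares["pre_only"] + shares["pre_and_post"]
        return GraftCloneCategories(
            subject_id=drtc.subject_id,
            subset=drtc.subset,
            labels=labels,
            counts=counts,
            shares=shares,
            cumulative_pre_share=cum_pre,
            three_way=False,
        )

    labels = pd.Series(
        np.where(pre.loc[universe], "pre_only", "undetermined"),
        index=pd.Index(universe, name="clone"),
        name="category",
    )
    counts = {c: int((labels == c).sum()) for c in categories}
    n = len(universe)
    shares = {c: counts[c] / n for c in categories}
    return GraftCloneCategories(
        subject_id=drtc.subject_id,
        subset=drtc.subset,
        labels=labels,
        counts=counts,
        shares=shares,
        cumulative_pre_share=shares["pre_only"],
        three_way=True,
    )


@dataclass
class UrineOverlapReport:
    """Urinary DRTC and their reappearance in later allograft biopsies."""

    subject_id: str
    subset: str
    urine_sample: str
    n_urine_detected: int
    n_also_in_biopsy: int
    detail: pd.DataFrame


def urine_graft_overlap(
    drtc,
    urine: RepertoireSample,
    later_biopsies: list[RepertoireSample],
) -> UrineOverlapReport:
    """Which urine-detected DRTC reappear in subsequent biopsies.

    The urine sample must chronologically precede every biopsy in the list.
    Returns the count of DRTC detected in the urine, the subset of those
    also detected in at least one later biopsy, and a per-clone detail
    table (clone, urine count, biopsy id, biopsy count).
    """
    t_urine = TIMEPOINT_ORDER.get(urine.timepoint, -1)
    for b in later_biopsies:
        if TIMEPOINT_ORDER.get(b.timepoint, 99) <= t_urine:
            raise ValueError(
                f"biopsy {b.sample_id!r} ({b.timepoint}) does not follow the "
                f"urine sample ({urine.timepoint})"
            )
    members = sorted(drtc.members)
    urine_counts = urine.counts.reindex(members, fill_value=0)
    urine_detected = [c for c in members if urine_counts[c] >= 1]
    rows = []
    hits: set[str] = set()
    for b in later_biopsies:
        bc = b.counts.reindex(urine_detected, fill_value=0)
        for clone in urine_detected:
            if bc[clone] >= 1:
                hits.add(clone)
                rows.append(
                    {
                        "clone": clone,
                        "urine_count": int(urine_counts[clone]),
                        "biopsy_id": b.sample_id,
                        "biopsy_count": int(bc[clone]),
                    }
                )
    detail = pd.DataFrame(rows, columns=["clone", "urine_count", "biopsy_id", "biopsy_count"])
    return UrineOverlapReport(
        subject_id=drtc.subject_id,
        subset=drtc.subset,
        urine_sample=urine.sample_id,
        n_urine_detected=len(urine_detected),
        n_also_in_biopsy=len(hits),
        detail=detail,
    )


def longitudinal_drtc_summary(
    drtc, samples: list[RepertoireSample]
) -> list[DRTCMetrics]:
    """Per-sample DRTC detection metrics ordered by timepoint.

    Suited for paired pre/post comparisons of the absolute number,
    breadth and depth of the DRTC set; samples are never imputed, a
    missing timepoint is simply not in the series.
    """
    ordered = sorted(samples, key=_sample_order_key)
    return [drtc_metrics(drtc, s) for s in ordered]
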