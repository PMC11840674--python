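"""Repertoire summaries, overlap indices, and DRTC detection metrics.

Overlap between two repertoires is quantified two ways, both scored 0
(completely divergent) to 1 (identical): the Morisita-Horn index, which
weights shared clones by their frequencies and is therefore robust to
sequencing depth, and the Jaccard index on clone sets, which ignores
abundance and degrades with shallow sampling. Using both separates "the
same dominant clones" from "the same clone list".

For a DRTC set tracked into a sample, ``n_detected`` counts the DRTC
present at >= 1 template, ``breadth`` is the fraction of the sample's
unique productive clonotypes that are DRTC, and ``depth`` is the summed
frequency of detected DRTC — the share of all T cells they occupy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DegenerateSampleError, RepertoireSample, clone_frequencies

__all__ = [
    "RepertoireSummary",
    "OverlapResult",
    "DRTCMetrics",
    "summarize_sample",
    "morisita_index",
    "jaccard_index",
    "overlap",
    "drtc_metrics",
    "tcell_fraction",
    "qc_pairwise",
]


@dataclass(frozen=True)
class RepertoireSummary:
    sample_id: str
    unique_productive_clonotypes: int
    total_templates: int
    tcell_fraction: float | None


@dataclass(frozen=True)
class OverlapResult:
    sample_a: str
    sample_b: str
    morisita: float
    jaccard: float
    shared_clonotypes: int


@dataclass(frozen=True)
class DRTCMetrics:
    sample_id: str
    subset: str
    n_detected: int
    breadth: float
    depth: float


def summarize_sample(sample: RepertoireSample) -> RepertoireSummary:
    return RepertoireSummary(
        sample_id=sample.sample_id,
        unique_productive_clonotypes=sample.n_productive_clonotypes,
        total_templates=sample.total_templates,
        tcell_fraction=tcell_fraction(sample),
    )


def morisita_index(sample_a: RepertoireSample, sample_b: RepertoireSample) -> float:
    """Morisita-Horn overlap on productive template frequencies.

    MH = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²) over the union of clone keys,
    clamped to [0, 1]. Equals 1 for identical frequency vectors and 0 for
    disjoint clone sets.
    """
    pa = clone_frequencies(sample_a)
    pb = clone_frequencies(sample_b)
    union = pa.index.union(pb.index, sort=False)
    p = pa.reindex(union, fill_value=0.0).to_numpy()
    q = pb.reindex(union, fill_value=0.0).to_numpy()
    denom = float(np.sum(p * p) + np.sum(q * q))
    if denom == 0.0:
        raise DegenerateSampleError("both samples are degenerate")
    return float(np.clip(2.0 * np.sum(p * q) / denom, 0.0, 1.0))


def jaccard_index(sample_a: RepertoireSample, sample_b: RepertoireSample) -> float:
    """Jaccard overlap |A ∩ B| / |A ∪ B| on productive clone-key sets."""
    a = set(sample_a.counts.index[sample_a.counts >= 1])
    b = set(sample_b.counts.index[sample_b.counts >= 1])
    if not a and not b:
        raise DegenerateSampleError("both samples have empty productive clone sets")
    return len(a & b) / len(a | b)


def overlap(sample_a: RepertoireSample, sample_b: RepertoireSample) -> OverlapResult:
    """Both overlap indices plus the shared-clonotype count for a pair."""
    a = set(sample_a.counts.index[sample_a.counts >= 1])
    b = set(sample_b.counts.index[sample_b.counts >= 1])
    return OverlapResult(
        sample_a=sample_a.sample_id,
        sample_b=sample_b.sample_id,
        morisita=morisita_index(sample_a, sample_b),
        jaccard=jaccard_index(sample_a, sample_b),
        shared_clonotypes=len(a & b),
    )


def drtc_metrics(drtc_members, sample: RepertoireSample, subset: str = "") -> DRTCMetrics:
    """Detection count, breadth and depth of a DRTC set within a sample.

    ``drtc_members`` is any iterable of clone keys (or a
    :class:`~allotrace.calling.DRTCSet`). Detection threshold is one
    template. An empty DRTC set yields (0, 0, 0) rather than an error.
    """
    if hasattr(drtc_members, "members"):
        if not subset:
            subset = drtc_members.subset
        drtc_members = drtc_members.members
    members = set(drtc_members)
    counts = sample.counts
    total = sample.total_templates
    if total <= 0:
        raise DegenerateSampleError(f"sample {sample.sample_id!r} has no productive templates")
    detected = counts.index.intersection(members)
    detected = detected[counts.loc[detected] >= 1]
    n_detected = int(len(detected))
    n_unique = sample.n_productive_clonotypes
    return DRTCMetrics(
        sample_id=sample.sample_id,
        subset=subset,
        n_detected=n_detected,
        breadth=n_detected / n_unique if n_unique else 0.0,
        depth=float(counts.loc[detected].sum()) / total,
    )


def tcell_fraction(sample: RepertoireSample) -> float | None:
    """Fraction of input genomes carrying a rearranged TCRβ locus.

    Estimated as productive templates / genome equivalents, clamped to
    [0, 1]. Returns ``None`` when genome equivalents were not recorded —
    the metric is reported as absent, never fabricated.
    """
    if sample.genome_equivalents is None:
        return None
    return float(np.clip(sample.total_templates / sample.genome_equivalents, 0.0, 1.0))


def qc_pairwise(
    samples: list[RepertoireSample], threshold: float = 0.2
) -> pd.DataFrame:
    """All-pairs overlap as a swap/contamination quality-control screen.

    Returns a long-format table (sample_a, sample_b, subject_a, subject_b,
    morisita, jaccard, shared_clonotypes, flagged) over unordered pairs. A
    pair from *different* subjects with Morisita-Horn above ``threshold``
    is flagged as a possible sample swap or material transfer; same-subject
    pairs are expected to overlap and are never flagged.
    """
    if len(samples) < 2:
        raise ValueError("qc_pairwise requires at least two samples")
    rows = []
    for sa, sb in itertools.combinations(samples, 2):
        ov = overlap(sa, sb)
        different = sa.subject_id != sb.subject_id
        rows.append(
            {
                "sample_a": sa.sample_id,
                "sample_b": sb.sample_id,
                "subject_a": sa.subject_id,
                "subject_b": sb.subject_id,
                "morisita": ov.morisita,
                "jaccard": ov.jaccard,
                "shared_clonotypes": ov.shared_clonotypes,
                "flagged": bool(different and ov.morisita > threshold),
            }
        )
    return pd.DataFrame(rows)
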