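"""End-to-end orchestration: per-subject DRTC analysis and cohort roll-ups.

Subjects are analyzed independently — DRTC are called per subject and per
sorted subset against that subject's own unstimulated pre-transplant PBMC,
and Benjamini-Hochberg multiplicity is never pooled across subjects. A
subject lacking the pre-transplant unstimulated sample or any MLR sort is
skipped with a logged reason; partial specimen sets produce partial
reports with explicit gaps, never imputation. When several biopsies exist
the earliest (first episode) anchors the graft categorization.

All outputs are tab-separated text with '#'-prefixed provenance header
lines echoing the calling parameters; nothing in an output file depends on
wall-clock time, so identical inputs and seed reproduce byte-identical
files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calling import DRTCSet, call_drtc
from .io import (
    TIMEPOINT_ORDER,
    RepertoireSample,
    SampleManifest,
    read_manifest,
)
from .metrics import drtc_metrics, morisita_index, jaccard_index, qc_pairwise, summarize_sample
from .stats import GroupComparison, mann_whitney_u, wilcoxon_signed_rank
from .tracking import (
    GraftCloneCategories,
    TrackingTable,
    UrineOverlapReport,
    build_tracking,
    categorize_graft_clones,
    longitudinal_drtc_summary,
    urine_graft_overlap,
)

__all__ = ["PipelineConfig", "SubjectReport", "run_subject", "run_cohort"]

log = logging.getLogger("allotrace")


@dataclass
class PipelineConfig:
    """Calling and reporting parameters, echoed verbatim into every output."""

    alpha: float = 0.01
    fold_min: float = 2.0
    count_floor: int = 5
    method: str = "minlike"
    qc_threshold: float = 0.2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def provenance(self) -> list[str]:
        return [f"# {k} = {v}" for k, v in asdict(self).items()]


@dataclass
class SubjectReport:
    subject_id: str
    induction_group: str = ""
    biopsy_status: str = ""
    drtc_sets: dict = field(default_factory=dict)  # subset -> DRTCSet
    tracking: dict = field(default_factory=dict)  # subset -> TrackingTable
    longitudinal: dict = field(default_factory=dict)  # subset -> [DRTCMetrics]
    categorization: dict = field(default_factory=dict)  # subset -> GraftCloneCategories
    urine_overlap: dict = field(default_factory=dict)  # subset -> [UrineOverlapReport]
    summaries: list = field(default_factory=list)
    pre_post_overlap: dict | None = None  # morisita/jaccard of pre vs post blood
    missing_sections: list = field(default_factory=list)


def _by_order(sample: RepertoireSample) -> tuple:
    return (TIMEPOINT_ORDER.get(sample.timepoint, 99), sample.sample_id)


def _find_roles(samples: list[RepertoireSample]):
    pre = [
        s
        for s in samples
        if s.compartment == "pbmc" and s.timepoint == "pre_tx" and s.subset == "bulk"
    ]
    mlr = {s.subset: s for s in samples if s.compartment == "mlr_sort"}
    posts = sorted(
        (s for s in samples if s.compartment == "pbmc" and s.timepoint != "pre_tx"),
        key=_by_order,
    )
    biopsies = sorted((s for s in samples if s.compartment == "biopsy"), key=_by_order)
    urines = sorted((s for s in samples if s.compartment == "urine"), key=_by_order)
    return (pre[0] if pre else None), mlr, posts, biopsies, urines


def run_subject_samples(
    samples: list[RepertoireSample],
    config: PipelineConfig | None = None,
    *,
    induction_group: str = "",
    biopsy_status: str = "",
) -> SubjectReport | None:
    """Analyze one subject from already-loaded samples.

    Returns ``None`` (with a logged reason) when the subject lacks the
    pre-transplant unstimulated PBMC or every MLR sort.
    """
    config = config or PipelineConfig()
    subject_id = next((s.subject_id for s in samples if s.subject_id), "")
    pre, mlr, posts, biopsies, urines = _find_roles(samples)
    if pre is None:
        log.warning("subject %s skipped: no pre-transplant unstimulated PBMC", subject_id)
        return None
    if not mlr:
        log.warning("subject %s skipped: no MLR-sorted sample", subject_id)
        return None

    report = SubjectReport(
        subject_id=subject_id,
        induction_group=induction_group,
        biopsy_status=biopsy_status,
    )
    report.summaries = [summarize_sample(s) for s in sorted(samples, key=_by_order)]
    post = posts[0] if posts else None
    first_biopsy = biopsies[0] if biopsies else None
    if post is not None:
        report.pre_post_overlap = {
            "morisita": morisita_index(pre, post),
            "jaccard": jaccard_index(pre, post),
        }
    else:
        report.missing_sections.append("pre_post_overlap")

    for subset in ("cd4", "cd8"):
        if subset not in mlr:
            report.missing_sections.append(f"drtc_{subset}")
            log.info("subject %s: no MLR-%s sample; subset skipped", subject_id, subset)
            continue
        drtc = call_drtc(
            mlr[subset],
            pre,
            alpha=config.alpha,
            fold_min=config.fold_min,
            count_floor=config.count_floor,
            method=config.method,
        )
        report.drtc_sets[subset] = drtc
        track_samples = [s for s in samples if s.compartment != "mlr_sort"]
        report.tracking[subset] = build_tracking(drtc, track_samples)
        blood = [pre] + posts
        report.longitudinal[subset] = longitudinal_drtc_summary(drtc, blood)
        if first_biopsy is not None:
            report.categorization[subset] = categorize_graft_clones(
                drtc, first_biopsy, pre, post
            )
        else:
            report.missing_sections.append(f"categorization_{subset}")
        overlaps = []
        for u in urines:
            later = [
                b
                for b in biopsies
                if TIMEPOINT_ORDER.get(b.timepoint, 99) > TIMEPOINT_ORDER.get(u.timepoint, -1)
            ]
            if later:
                overlaps.append(urine_graft_overlap(drtc, u, later))
        if overlaps:
            report.urine_overlap[subset] = overlaps
        else:
            report.missing_sections.append(f"urine_overlap_{subset}")
    return report


def run_subject(
    manifest: SampleManifest, subject_id: str, config: PipelineConfig | None = None
) -> SubjectReport | None:
    """Load a subject's samples from a manifest and analyze them."""
    rows = manifest.subject_rows(subject_id)
    if rows.empty:
        raise ValueError(f"subject {subject_id!r} not in manifest")
    samples = list(manifest.iter_samples(subject_id))
    induction = rows["induction_group"].iloc[0]
    status = rows["biopsy_status"].iloc[0]
    return run_subject_samples(
        samples, config, induction_group=induction, biopsy_status=status
    )


# ---------------------------------------------------------------- reporting


def _write_tsv(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _drtc_table(drtc: DRTCSet) -> pd.DataFrame:
    out = drtc.results.reset_index()
    out["fold"] = out["fold"].map(lambda v: "inf" if v == float("inf") else v)
    return out


def write_subject_report(report: SubjectReport, out_dir: Path, config: PipelineConfig) -> None:
    prov = config.provenance() + [f"# subject = {report.subject_id}"]
    sdir = out_dir / report.subject_id
    for subset, drtc in sorted(report.drtc_sets.items()):
        _write_tsv(_drtc_table(drtc), sdir / f"drtc_{subset}.tsv", prov)
    for subset, track in sorted(report.tracking.items()):
        _write_tsv(track.to_long(), sdir / f"tracking_{subset}.tsv", prov)
    cat_rows = []
    for subset, cat in sorted(report.categorization.items()):
        for category, count in sorted(cat.counts.items()):
            cat_rows.append(
                {
                    "subset": subset,
                    "category": category,
                    "count": count,
                    "share": "" if cat.shares is None else cat.shares[category],
                    "cumulative_pre_share": (
                        "" if cat.cumulative_pre_share is None else cat.cumulative_pre_share
                    ),
                    "three_way": cat.three_way,
                }
            )
    if cat_rows:
        _write_tsv(pd.DataFrame(cat_rows), sdir / "categorization.tsv", prov)
    urine_rows = []
    for subset, reports in sorted(report.urine_overlap.items()):
        for rep in reports:
            urine_rows.append(
                {
                    "subset": subset,
                    "urine_sample": rep.urine_sample,
                    "n_urine_detected": rep.n_urine_detected,
                    "n_also_in_biopsy": rep.n_also_in_biopsy,
                }
            )
    if urine_rows:
        _write_tsv(pd.DataFrame(urine_rows), sdir / "urine_overlap.tsv", prov)


def _comparison_row(cmp: GroupComparison, subset: str = "") -> dict:
    return {
        "metric": cmp.metric,
        "subset": subset,
        "test": cmp.test,
        "group_a": cmp.group_labels[0],
        "group_b": cmp.group_labels[-1],
        "n_a": cmp.group_sizes[0],
        "n_b": cmp.group_sizes[-1],
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "median_a": cmp.medians[0],
        "median_b": cmp.medians[-1],
        "degenerate": cmp.degenerate,
    }


def run_cohort(
    manifest: SampleManifest,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Analyze every subject in a manifest and write cohort roll-ups.

    Produces per-subject report files plus cohort-level tables:
    tidy DRTC metrics, graft-clone categorization, urine→biopsy overlap,
    pre↔post blood similarity, swap-screen QC over blood samples, and
    group comparisons stratified by induction group and biopsy status.
    Returns the reports and roll-up frames in a dict.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    prov = config.provenance()

    reports: dict[str, SubjectReport] = {}
    for subject_id in manifest.subjects:
        rep = run_subject(manifest, subject_id, config)
        if rep is not None:
            reports[subject_id] = rep
            write_subject_report(rep, out_dir, config)

    metric_rows, cat_rows, urine_rows, overlap_rows, summary_rows = [], [], [], [], []
    for subject_id, rep in sorted(reports.items()):
        meta = {
            "subject_id": subject_id,
            "induction_group": rep.induction_group,
            "biopsy_status": rep.biopsy_status,
        }
        for s in rep.summaries:
            summary_rows.append(
                {
                    **meta,
                    "sample_id": s.sample_id,
                    "unique_productive_clonotypes": s.unique_productive_clonotypes,
                    "total_templates": s.total_templates,
                    "tcell_fraction": "" if s.tcell_fraction is None else s.tcell_fraction,
                }
            )
        for subset, track in sorted(rep.tracking.items()):
            drtc = rep.drtc_sets[subset]
            for _, srow in track.sample_meta.iterrows():
                sample_cols = track.counts[srow["sample_id"]]
                n_det = int((sample_cols >= 1).sum())
                depth = float(track.frequencies[srow["sample_id"]].sum())
                metric_rows.append(
                    {
                        **meta,
                        "subset": subset,
                        "sample_id": srow["sample_id"],
                        "timepoint": srow["timepoint"],
                        "compartment": srow["compartment"],
                        "n_drtc_defined": len(drtc),
                        "n_detected": n_det,
                        "depth": depth,
                    }
                )
        for subset, cat in sorted(rep.categorization.items()):
            for category, count in sorted(cat.counts.items()):
                cat_rows.append(
                    {
                        **meta,
                        "subset": subset,
                        "category": category,
                        "count": count,
                        "share": "" if cat.shares is None else cat.shares[category],
                        "cumulative_pre_share": (
                            "" if cat.cumulative_pre_share is None else cat.cumulative_pre_share
                        ),
                        "three_way": cat.three_way,
                    }
                )
        for subset, overlaps in sorted(rep.urine_overlap.items()):
            for ov in overlaps:
                urine_rows.append(
                    {
                        **meta,
                        "subset": subset,
                        "urine_sample": ov.urine_sample,
                        "n_urine_detected": ov.n_urine_detected,
                        "n_also_in_biopsy": ov.n_also_in_biopsy,
                    }
                )
        if rep.pre_post_overlap is not None:
            overlap_rows.append({**meta, **rep.pre_post_overlap})

    rollups = {
        "summaries": pd.DataFrame(summary_rows),
        "drtc_metrics": pd.DataFrame(metric_rows),
        "categorization": pd.DataFrame(cat_rows),
        "urine_overlap": pd.DataFrame(urine_rows),
        "pre_post_overlap": pd.DataFrame(overlap_rows),
    }
    for name, df in rollups.items():
        _write_tsv(df, out_dir / f"cohort_{name}.tsv", prov)

    # blood-sample swap screen
    blood = [
        manifest.load_sample(sid)
        for sid in manifest.rows.loc[manifest.rows["compartment"] == "pbmc", "sample_id"]
    ]
    if len(blood) >= 2:
        qc = qc_pairwise(blood, threshold=config.qc_threshold)
        _write_tsv(qc, out_dir / "qc_pairwise.tsv", prov)
        rollups["qc_pairwise"] = qc

    comparisons = _cohort_comparisons(rollups, reports)
    _write_tsv(comparisons, out_dir / "cohort_comparisons.tsv", prov)
    rollups["comparisons"] = comparisons
    rollups["reports"] = reports
    return rollups


def _cohort_comparisons(rollups: dict, reports: dict) -> pd.DataFrame:
    """Group tests over the cohort roll-ups (skipped when groups are thin)."""
    rows: list[dict] = []
    metrics = rollups["drtc_metrics"]
    overlap = rollups["pre_post_overlap"]

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as err:
            log.warning("comparison skipped: %s", err)
            return None

    if not overlap.empty:
        groups = overlap.groupby("induction_group")["morisita"]
        if {"campath", "non_campath"} <= set(overlap["induction_group"]):
            a = groups.get_group("campath").to_numpy()
            b = groups.get_group("non_campath").to_numpy()
            if a.size >= 2 and b.size >= 2:
                cmp = safe(
                    mann_whitney_u,
                    a,
                    b,
                    metric="pre_post_morisita",
                    labels=("campath", "non_campath"),
                )
                if cmp:
                    rows.append(_comparison_row(cmp))

    if not metrics.empty:
        for subset in sorted(metrics["subset"].unique()):
            sub = metrics[metrics["subset"] == subset]
            # paired pre vs post blood detection, per induction group
            blood = sub[sub["compartment"] == "pbmc"]
            for group in sorted(blood["induction_group"].unique()):
                g = blood[blood["induction_group"] == group]
                pre = g[g["timepoint"] == "pre_tx"].set_index("subject_id")
                post = g[g["timepoint"] != "pre_tx"].set_index("subject_id")
                paired = pre.index.intersection(post.index)
                if len(paired) >= 2:
                    for col in ("n_detected", "depth"):
                        cmp = safe(
                            wilcoxon_signed_rank,
                            pre.loc[paired, col].to_numpy(),
                            post.loc[paired, col].to_numpy(),
                            metric=f"{col}_pre_vs_post_{group}",
                        )
                        if cmp:
                            rows.append(_comparison_row(cmp, subset))
            # rejection vs stable: pre-transplant depth and biopsy detection
            for compartment, timefilter, col, name in (
                ("pbmc", "pre_tx", "depth", "pretx_depth"),
                ("biopsy", None, "n_detected", "biopsy_n_detected"),
            ):
                g = sub[sub["compartment"] == compartment]
                if timefilter:
                    g = g[g["timepoint"] == timefilter]
                rej = g[g["biopsy_status"] == "acute_rejection"][col].to_numpy()
                stab = g[g["biopsy_status"] == "stable"][col].to_numpy()
                if rej.size >= 2 and stab.size >= 2:
                    cmp = safe(
                        mann_whitney_u,
                        rej,
                        stab,
                        metric=f"{name}_rejection_vs_stable",
                        labels=("acute_rejection", "stable"),
                    )
                    if cmp:
                        rows.append(_comparison_row(cmp, subset))
    columns = [
        "metric",
        "subset",
        "test",
        "group_a",
        "group_b",
        "n_a",
        "n_b",
        "statistic",
        "p_value",
        "median_a",
        "median_b",
        "degenerate",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_cohort_from_path(
    manifest_path: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> dict:
    return run_cohort(read_manifest(manifest_path), out_dir, config)
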