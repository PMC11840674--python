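"""Simulation experiments that measure the DRTC caller against ground truth.

These routines quantify the operating characteristics of the
differential-abundance definition under known generative conditions:

* :func:`null_fdr_experiment` — paired samples drawn from one shared clone
  distribution (no true enrichment): how often does the caller fire, and
  what is the realized false-discovery proportion among gated clones?
* :func:`spike_in_experiment` — a known set of clones is expanded by a
  fixed fold at frequencies high enough to be sequenced reliably: what
  fraction is recovered (sensitivity), and how many calls are false (FDR)?
* :func:`cohort_patterns` — group-level contrasts on a full synthetic
  cohort (induction-therapy repertoire contraction, rejection-associated
  circulating CD8⁺ alloreactive burden, graft infiltration, urinary
  shedding), the qualitative patterns the longitudinal analysis is built
  to detect.

Ground truth is consumed only here — never by the analysis path.
"""

from __future__ import annotations

import numpy as np

from .calling import call_drtc
from .io import RepertoireSample
from .metrics import drtc_metrics, morisita_index
from .simulate import SimulationConfig, SubjectData, simulate_cohort
from .tracking import categorize_graft_clones, urine_graft_overlap

__all__ = [
    "null_fdr_experiment",
    "spike_in_experiment",
    "cohort_patterns",
]


def _zipf(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -s
    return w / w.sum()


def _pair_from_weights(
    rng: np.random.Generator,
    w_a: np.ndarray,
    w_b: np.ndarray,
    depth_a: int,
    depth_b: int,
) -> tuple[RepertoireSample, RepertoireSample]:
    names = [f"c{i}" for i in range(w_a.size)]
    ca = rng.multinomial(depth_a, w_a / w_a.sum())
    cb = rng.multinomial(depth_b, w_b / w_b.sum())
    a = RepertoireSample.from_counts("a", {names[i]: int(v) for i, v in enumerate(ca) if v})
    b = RepertoireSample.from_counts("b", {names[i]: int(v) for i, v in enumerate(cb) if v})
    return a, b


def null_fdr_experiment(
    n_replicates: int = 200,
    *,
    seed: int = 0,
    n_clones: int = 5000,
    zipf_exponent: float = 1.5,
    depth: int = 50_000,
    alpha: float = 0.01,
) -> dict:
    """False-discovery behaviour when no clone is truly enriched.

    Both samples of each replicate are independent multinomial draws from
    one shared Zipf clone distribution, so every DRTC call is a false
    discovery. Returns the median number of calls per replicate, the mean
    false-discovery proportion among clones passing all gates, and the
    per-replicate call counts.
    """
    rng = np.random.default_rng(seed)
    base = _zipf(n_clones, zipf_exponent)
    calls = np.zeros(n_replicates, dtype=int)
    fdp = np.zeros(n_replicates)
    tested = np.zeros(n_replicates, dtype=int)
    for r in range(n_replicates):
        a, b = _pair_from_weights(rng, base, base, depth, depth)
        drtc = call_drtc(a, b, alpha=alpha)
        n_called = len(drtc)
        calls[r] = n_called
        tested[r] = int((drtc.results["call"] != "below_count_floor").sum())
        fdp[r] = n_called / max(n_called, 1)  # all calls are false under the null
    return {
        "median_calls": float(np.median(calls)),
        "mean_fdp": float(fdp.mean()),
        "mean_calls": float(calls.mean()),
        "mean_tested": float(tested.mean()),
        "calls": calls,
    }


def spike_in_experiment(
    n_replicates: int = 50,
    *,
    seed: int = 0,
    n_clones: int = 2000,
    n_spiked: int = 50,
    fold: float = 8.0,
    zipf_exponent: float = 1.5,
    depth_mlr: int = 20_000,
    depth_unstim: int = 50_000,
    min_expected_count: float = 20.0,
    alpha: float = 0.01,
) -> dict:
    """Recovery of clones expanded by a known fold.

    ``n_spiked`` clones are placed at baseline frequencies high enough
    that their expected MLR template count after a ``fold``-fold expansion
    is at least ``min_expected_count``; sensitivity is measured over
    exactly those clones, and FDR over all calls against ground truth.
    """
    rng = np.random.default_rng(seed)
    base = _zipf(n_clones, zipf_exponent)
    # spike mid-rank clones: abundant enough to be sequenced, not dominant
    spiked = np.arange(20, 20 + n_spiked)
    w_mlr = base.copy()
    w_mlr[spiked] *= fold
    w_mlr /= w_mlr.sum()
    expected = w_mlr[spiked] * depth_mlr
    if expected.min() < min_expected_count:
        raise ValueError(
            f"spike construction too shallow: min expected MLR count {expected.min():.1f}"
        )
    truth = {f"c{i}" for i in spiked}
    sens = np.zeros(n_replicates)
    fdr = np.zeros(n_replicates)
    for r in range(n_replicates):
        mlr, unstim = _pair_from_weights(rng, w_mlr, base, depth_mlr, depth_unstim)
        drtc = call_drtc(mlr, unstim, alpha=alpha)
        called = set(drtc.members)
        sens[r] = len(called & truth) / len(truth)
        fdr[r] = len(called - truth) / max(len(called), 1)
    return {
        "sensitivity": float(sens.mean()),
        "fdr": float(fdr.mean()),
        "sensitivity_per_replicate": sens,
        "fdr_per_replicate": fdr,
    }


def cohort_patterns(subjects: list[SubjectData], *, alpha: float = 0.01) -> dict:
    """Group-level contrasts on a synthetic cohort, per subject.

    For every subject: call CD4⁺/CD8⁺ DRTC, compute the pre↔post blood
    Morisita-Horn index, pre-transplant CD8⁺ DRTC depth, biopsy DRTC
    detection counts, graft-clone categorization and the urine→biopsy
    overlap. Returns per-group medians for the rejection- and
    induction-stratified comparisons.
    """
    rows = []
    for subj in subjects:
        pre = subj.samples["pre_pbmc"]
        post = subj.samples["post_pbmc"]
        biopsy = subj.samples["biopsy"]
        urine = subj.samples["urine"]
        rec = {
            "subject_id": subj.subject_id,
            "induction_group": subj.induction_group,
            "biopsy_status": subj.biopsy_status,
            "pre_post_morisita": morisita_index(pre, post),
        }
        for subset in ("cd4", "cd8"):
            drtc = call_drtc(subj.samples[f"mlr_{subset}"], pre, alpha=alpha)
            rec[f"n_drtc_{subset}"] = len(drtc)
            rec[f"pretx_depth_{subset}"] = drtc_metrics(drtc, pre).depth
            rec[f"biopsy_n_detected_{subset}"] = drtc_metrics(drtc, biopsy).n_detected
            cat = categorize_graft_clones(drtc, biopsy, pre, post)
            rec[f"cumulative_pre_share_{subset}"] = cat.cumulative_pre_share
            rec[f"post_only_share_{subset}"] = (
                None if cat.shares is None else cat.shares["post_only"]
            )
            if biopsy.timepoint != "wk2":
                ov = urine_graft_overlap(drtc, urine, [biopsy])
                rec[f"urine_detected_{subset}"] = ov.n_urine_detected
                rec[f"urine_biopsy_overlap_{subset}"] = ov.n_also_in_biopsy
        rows.append(rec)

    def med(key, group_key, group_value):
        vals = [
            r[key]
            for r in rows
            if r[group_key] == group_value and r.get(key) is not None
        ]
        return float(np.median(vals)) if vals else float("nan")

    return {
        "per_subject": rows,
        "median_morisita_campath": med("pre_post_morisita", "induction_group", "campath"),
        "median_morisita_non_campath": med(
            "pre_post_morisita", "induction_group", "non_campath"
        ),
        "median_pretx_cd8_depth_rejection": med(
            "pretx_depth_cd8", "biopsy_status", "acute_rejection"
        ),
        "median_pretx_cd8_depth_stable": med("pretx_depth_cd8", "biopsy_status", "stable"),
        "median_biopsy_cd8_detected_rejection": med(
            "biopsy_n_detected_cd8", "biopsy_status", "acute_rejection"
        ),
        "median_biopsy_cd8_detected_stable": med(
            "biopsy_n_detected_cd8", "biopsy_status", "stable"
        ),
        "urine_overlap_rejection": sum(
            r.get("urine_biopsy_overlap_cd4", 0) + r.get("urine_biopsy_overlap_cd8", 0)
            for r in rows
            if r["biopsy_status"] == "acute_rejection"
        ),
        "urine_overlap_stable": sum(
            r.get("urine_biopsy_overlap_cd4", 0) + r.get("urine_biopsy_overlap_cd8", 0)
            for r in rows
            if r["biopsy_status"] == "stable"
        ),
    }
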