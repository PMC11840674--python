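"""Synthetic kidney-transplant cohort generator.

Emulates the statistical structure the DRTC analysis assumes, so every
stage of the pipeline is testable end-to-end without patient data:

* a per-subject clone-size law (Zipf, exponent 1.5) over ~10,000 TCRβ
  clonotypes, with template counts drawn multinomially at compartment-
  specific sequencing depths;
* a small alloreactive fraction (default 2%, split 2:1 CD4:CD8) whose
  clones are multiplied by log-normal expansion factors in the MLR-sorted
  samples;
* induction therapy as post-transplant clone removal (lymphodepleting
  "Campath": 90% of clones removed; non-lymphodepleting: 10%);
* rejection as graft infiltration of the pre-transplant circulating
  alloreactive pool (over-representation in the biopsy) plus an elevated
  pre-transplant CD8⁺ alloreactive frequency, and early urinary shedding
  of graft-infiltrating clones.

Urine in stable subjects contains only a urine-resident background pool,
never blood clones: clinically, stable allografts shed few T cells, and
this makes the urine→biopsy overlap a clean rejection signal. Ground truth
(the alloreactive clone keys and every generative frequency vector) is
recorded before sampling noise and is never consumed by the analysis path.

Clone identity strings are random in-frame 87-mers over ACGT; CDR3/V/J
annotations are synthetic placeholders — identity, not sequence content,
drives every downstream computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import RepertoireSample, SampleManifest, read_manifest, write_clonotype_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SubjectData",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    Depths are template counts per sample (PBMC 100,000; MLR sort 20,000;
    biopsy 3,000; urine 500). ``campath_depletion`` is the fraction of a
    subject's clones absent from the post-transplant blood. The MLR
    expansion factor is log-normal with the given median.
    """

    n_subjects: int = 12
    seed: int = 0
    n_clones: int = 10_000
    zipf_exponent: float = 1.5
    alloreactive_fraction: float = 0.02
    cd4_share: float = 2.0 / 3.0  # CD4:CD8 alloreactive split, 2:1
    mlr_expansion_median: float = 8.0
    mlr_expansion_sigma: float = 0.6
    depth_pbmc: int = 100_000
    depth_mlr: int = 20_000
    depth_biopsy: int = 3_000
    depth_urine: int = 500
    campath_fraction: float = 2.0 / 3.0
    campath_depletion: float = 0.9
    non_campath_depletion: float = 0.1
    rejection_fraction: float = 0.25
    graft_infiltration_factor: float = 20.0
    rejection_cd8_pretx_boost: float = 5.0
    urine_shedding_fraction: float = 0.5
    urine_background_clones: int = 50
    urine_background_mass: float = 0.5
    nonproductive_fraction: float = 0.03
    tcell_fraction_pbmc: float = 0.25
    tcell_fraction_biopsy: float = 0.05
    tcell_fraction_urine: float = 0.02

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "alloreactive_fraction": self.alloreactive_fraction,
            "cd4_share": self.cd4_share,
            "campath_fraction": self.campath_fraction,
            "campath_depletion": self.campath_depletion,
            "non_campath_depletion": self.non_campath_depletion,
            "rejection_fraction": self.rejection_fraction,
            "urine_shedding_fraction": self.urine_shedding_fraction,
            "urine_background_mass": self.urine_background_mass,
            "nonproductive_fraction": self.nonproductive_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]; got {value}")
        depths = {
            "depth_pbmc": self.depth_pbmc,
            "depth_mlr": self.depth_mlr,
            "depth_biopsy": self.depth_biopsy,
            "depth_urine": self.depth_urine,
        }
        for name, value in depths.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive; got {value}")
            if value > 1000 * self.n_clones:
                raise ConfigError(
                    f"{name}={value} exceeds a plausible template yield for "
                    f"{self.n_clones} clones"
                )
        if self.n_clones < 10:
            raise ConfigError("n_clones must be at least 10")
        if self.zipf_exponent <= 0:
            raise ConfigError("zipf_exponent must be positive")
        if self.n_subjects < 0:
            raise ConfigError("n_subjects must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must rediscover."""

    subject_id: str
    allo_cd4: list[str]
    allo_cd8: list[str]
    #: sample_id -> generative frequency Series over the clones with mass
    generative_freqs: dict = field(default_factory=dict)


@dataclass
class SubjectData:
    subject_id: str
    induction_group: str
    biopsy_status: str
    samples: dict  # sample role -> RepertoireSample
    truth: GroundTruth


_NT = np.frombuffer(b"ACGT", dtype="S1")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # child seed derivation: SeedSequence(root).spawn-like, but explicit and
    # stable — subject i always gets spawn_key (i,) under the same root seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(subject_index,)))


def _random_rearrangements(rng: np.random.Generator, n: int, length: int = 87) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        block = _NT[rng.integers(0, 4, size=(n - len(seqs), length))]
        for row in block:
            s = row.tobytes().decode()
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


def _annotations(rng: np.random.Generator, n: int, productive: np.ndarray):
    aa = np.array(list(_AA))
    cdr3 = ["C" + "".join(rng.choice(aa, size=10)) + "F" for _ in range(n)]
    for i in np.flatnonzero(~productive):
        pos = int(rng.integers(1, 11))
        cdr3[i] = cdr3[i][:pos] + "*" + cdr3[i][pos + 1:]
    v = [f"TCRBV{int(k):02d}-01" for k in rng.integers(2, 31, size=n)]
    j = [f"TCRBJ0{int(k)}-0{int(m)}" for k, m in zip(rng.integers(1, 3, size=n), rng.integers(1, 8, size=n))]
    return cdr3, v, j


def _zipf_probs(rng: np.random.Generator, n: int, s: float) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** -s
    return w / w.sum()


def _sample_counts(rng: np.random.Generator, weights: np.ndarray, depth: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ConfigError("generative weights sum to zero")
    return rng.multinomial(depth, w / total)


def _make_sample(
    sample_id: str,
    subject_id: str,
    rearr: list[str],
    cdr3: list[str],
    v: list[str],
    j: list[str],
    productive: np.ndarray,
    counts: np.ndarray,
    *,
    timepoint: str,
    compartment: str,
    subset: str,
    tcell_fraction: float | None,
) -> RepertoireSample:
    keep = counts > 0
    idx = np.flatnonzero(keep)
    table = pd.DataFrame(
        {
            "cdr3_aa": [cdr3[i] for i in idx],
            "v_gene": [v[i] for i in idx],
            "j_gene": [j[i] for i in idx],
            "productive": productive[idx],
            "templates": counts[idx].astype(np.int64),
        },
        index=pd.Index([rearr[i] for i in idx], name="rearrangement"),
    )
    ge = None
    if tcell_fraction is not None:
        total = int(table.loc[table["productive"], "templates"].sum())
        ge = max(1, int(round(total / tcell_fraction))) if total else None
    return RepertoireSample(
        sample_id=sample_id,
        table=table,
        subject_id=subject_id,
        timepoint=timepoint,
        compartment=compartment,
        subset=subset,
        genome_equivalents=ge,
    )


def subject_group_labels(config: SimulationConfig, i: int) -> tuple[str, str]:
    """Deterministic induction/biopsy-status assignment for subject i.

    Subjects are interleaved so both induction groups contain rejection
    subjects: roughly ``campath_fraction`` receive Campath and roughly
    ``rejection_fraction`` develop an acute-rejection biopsy.
    """
    if abs(config.campath_fraction - 2 / 3) <= 1e-9:
        # interleave: two Campath subjects per cycle of three
        induction = "campath" if (i % 3) != 2 else "non_campath"
    else:
        n_campath = int(round(config.campath_fraction * max(config.n_subjects, 1)))
        induction = "campath" if i < n_campath else "non_campath"
    step = max(2, int(round(1.0 / config.rejection_fraction))) if config.rejection_fraction > 0 else 0
    rejection = step > 0 and (i % step) == step - 1
    return induction, ("acute_rejection" if rejection else "stable")


def simulate_subject(config: SimulationConfig, subject_index: int) -> SubjectData:
    """Generate one subject's specimen set plus ground truth.

    Produces the unstimulated pre-transplant PBMC, MLR-sorted CD4⁺ and
    CD8⁺ samples, a 3-month post-transplant PBMC, an allograft biopsy
    (timepoint ``rejection`` for rejection subjects, ``m3`` protocol biopsy
    otherwise) and a 2-week urine sample. Deterministic for a fixed
    (config.seed, subject_index).
    """
    config.validate()
    rng = _subject_rng(config.seed, subject_index)
    subject_id = f"S{subject_index + 1:03d}"
    induction, biopsy_status = subject_group_labels(config, subject_index)
    rejection = biopsy_status == "acute_rejection"
    depletion = (
        config.campath_depletion if induction == "campath" else config.non_campath_depletion
    )

    n = config.n_clones
    rearr = _random_rearrangements(rng, n)
    productive = rng.random(n) >= config.nonproductive_fraction
    cdr3, v, j = _annotations(rng, n, productive)

    base = _zipf_probs(rng, n, config.zipf_exponent)

    prod_idx = np.flatnonzero(productive)
    n_allo = int(round(config.alloreactive_fraction * n))
    allo = rng.choice(prod_idx, size=min(n_allo, prod_idx.size), replace=False)
    n_cd4 = int(round(config.cd4_share * allo.size))
    allo_cd4 = np.sort(allo[:n_cd4])
    allo_cd8 = np.sort(allo[n_cd4:])

    # pre-transplant repertoire; rejection subjects carry an elevated
    # circulating CD8+ alloreactive burden
    f0 = base.copy()
    if rejection and allo_cd8.size:
        f0[allo_cd8] *= config.rejection_cd8_pretx_boost
    f0 /= f0.sum()

    truth = GroundTruth(
        subject_id=subject_id,
        allo_cd4=[rearr[i] for i in allo_cd4],
        allo_cd8=[rearr[i] for i in allo_cd8],
    )
    samples: dict[str, RepertoireSample] = {}

    def add(role, sample_id, weights, depth, **kw):
        counts = _sample_counts(rng, weights, depth)
        samples[role] = _make_sample(
            sample_id, subject_id, rearr, cdr3, v, j, productive, counts, **kw
        )
        wsum = weights.sum()
        nz = weights > 0
        truth.generative_freqs[sample_id] = pd.Series(
            weights[nz] / wsum, index=[rearr[i] for i in np.flatnonzero(nz)]
        )

    add(
        "pre_pbmc",
        f"{subject_id}_pre_pbmc",
        f0,
        config.depth_pbmc,
        timepoint="pre_tx",
        compartment="pbmc",
        subset="bulk",
        tcell_fraction=config.tcell_fraction_pbmc,
    )

    # MLR sorts: alloreactive clones multiplied by log-normal expansion factors
    mu = np.log(config.mlr_expansion_median)
    for subset, allo_set in (("cd4", allo_cd4), ("cd8", allo_cd8)):
        w = f0.copy()
        if allo_set.size:
            w[allo_set] *= rng.lognormal(mu, config.mlr_expansion_sigma, size=allo_set.size)
        add(
            f"mlr_{subset}",
            f"{subject_id}_mlr_{subset}",
            w,
            config.depth_mlr,
            timepoint="pre_tx",
            compartment="mlr_sort",
            subset=subset,
            tcell_fraction=None,
        )

    # post-transplant blood: induction removes a fraction of clones outright
    removed = rng.random(n) < depletion
    w_post = np.where(removed, 0.0, f0)
    if w_post.sum() <= 0:
        w_post = f0.copy()  # pathological depletion=1; keep repertoire nonempty
    add(
        "post_pbmc",
        f"{subject_id}_post_pbmc_m3",
        w_post,
        config.depth_pbmc,
        timepoint="m3",
        compartment="pbmc",
        subset="bulk",
        tcell_fraction=config.tcell_fraction_pbmc,
    )

    # biopsy: rejection spikes the graft with the pre-transplant circulating
    # alloreactive pool, regardless of post-transplant blood depletion
    w_biopsy = w_post.copy()
    if rejection and allo.size:
        w_biopsy[allo] = f0[allo] * config.graft_infiltration_factor
    add(
        "biopsy",
        f"{subject_id}_biopsy",
        w_biopsy,
        config.depth_biopsy,
        timepoint="rejection" if rejection else "m3",
        compartment="biopsy",
        subset="bulk",
        tcell_fraction=config.tcell_fraction_biopsy,
    )

    # 2-week urine: shed graft-infiltrating alloreactive clones (rejection
    # only) over a urine-resident background pool of fresh clonotypes
    n_bg = config.urine_background_clones
    bg_rearr = _random_rearrangements(rng, n_bg)
    bg_prod = np.ones(n_bg, dtype=bool)
    bg_cdr3, bg_v, bg_j = _annotations(rng, n_bg, bg_prod)
    u_rearr = rearr + bg_rearr
    u_cdr3, u_v, u_j = cdr3 + bg_cdr3, v + bg_v, j + bg_j
    u_prod = np.concatenate([productive, bg_prod])
    w_urine = np.zeros(n + n_bg)
    shed_mass = 0.0
    if rejection and allo.size:
        n_shed = max(1, int(round(config.urine_shedding_fraction * allo.size)))
        shed = rng.choice(allo, size=n_shed, replace=False)
        shed_w = w_biopsy[shed]
        if shed_w.sum() > 0:
            shed_mass = 1.0 - config.urine_background_mass
            w_urine[shed] = shed_w / shed_w.sum() * shed_mass
    w_urine[n:] = (1.0 - shed_mass) / n_bg
    counts_u = _sample_counts(rng, w_urine, config.depth_urine)
    samples["urine"] = _make_sample(
        f"{subject_id}_urine_wk2",
        subject_id,
        u_rearr,
        u_cdr3,
        u_v,
        u_j,
        u_prod,
        counts_u,
        timepoint="wk2",
        compartment="urine",
        subset="bulk",
        tcell_fraction=config.tcell_fraction_urine,
    )
    truth.generative_freqs[f"{subject_id}_urine_wk2"] = pd.Series(
        w_urine[w_urine > 0] / w_urine.sum(),
        index=[u_rearr[i] for i in np.flatnonzero(w_urine > 0)],
    )

    return SubjectData(
        subject_id=subject_id,
        induction_group=induction,
        biopsy_status=biopsy_status,
        samples=samples,
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> list[SubjectData]:
    """Generate the whole cohort in memory (deterministic per config.seed)."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]


def write_cohort(subjects: list[SubjectData], out_dir: str | Path) -> SampleManifest:
    """Write clonotype tables, a manifest and a ground-truth sidecar to disk.

    One directory per subject; the manifest (``manifest.tsv``) uses paths
    relative to ``out_dir`` and the internal immunoSEQ-style dialect. The
    sidecar ``ground_truth.json`` records the alloreactive clone keys per
    subject; it is for evaluation only and is never read by the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    if not subjects:
        warnings.warn("writing an empty cohort manifest", stacklevel=2)
    for subj in subjects:
        sdir = out_dir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for sample in subj.samples.values():
            rel = Path(subj.subject_id) / f"{sample.sample_id}.tsv"
            write_clonotype_table(sample, out_dir / rel)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "path": str(rel),
                    "subject_id": subj.subject_id,
                    "timepoint": sample.timepoint,
                    "compartment": sample.compartment,
                    "subset": sample.subset,
                    "induction_group": subj.induction_group,
                    "biopsy_status": subj.biopsy_status,
                    "genome_equivalents": (
                        "" if sample.genome_equivalents is None else sample.genome_equivalents
                    ),
                }
            )
        truth[subj.subject_id] = {
            "allo_cd4": subj.truth.allo_cd4,
            "allo_cd8": subj.truth.allo_cd8,
            "induction_group": subj.induction_group,
            "biopsy_status": subj.biopsy_status,
        }
    manifest = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "path",
            "subject_id",
            "timepoint",
            "compartment",
            "subset",
            "induction_group",
            "biopsy_status",
            "genome_equivalents",
        ],
    )
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    if subjects:
        return read_manifest(manifest_path)
    return SampleManifest(rows=manifest.astype(str), base_dir=out_dir)
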