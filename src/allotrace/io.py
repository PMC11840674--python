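"""Reading and writing TCRβ clonotype tables and sample manifests.

Two tab-separated column dialects are supported and normalized to one
internal representation:

* ``immunoseq`` — ``rearrangement, amino_acid, v_gene, j_gene, templates,
  frame_type`` (the Adaptive immunoSEQ export style);
* ``airr``      — ``sequence, junction_aa, v_call, j_call, duplicate_count,
  productive`` (AIRR-community style names).

The unit of clone identity throughout the package is the nucleotide
rearrangement string: template counts are genomic-DNA molecule counts, and
nucleotide identity avoids convergent-CDR3 collisions when tracking clones
across samples. Non-productive rearrangements are parsed and retained with
``productive=False`` but are excluded from every total, frequency, test and
overlap index downstream.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "RepertoireSample",
    "SampleManifest",
    "read_clonotype_table",
    "write_clonotype_table",
    "clone_frequencies",
    "read_manifest",
    "DialectError",
    "RecordError",
    "ManifestError",
    "DegenerateSampleError",
    "TIMEPOINTS",
    "TIMEPOINT_ORDER",
    "COMPARTMENTS",
    "SUBSETS",
    "INDUCTION_GROUPS",
    "BIOPSY_STATUSES",
]


class DialectError(ValueError):
    """A clonotype table does not match any supported column dialect."""


class RecordError(ValueError):
    """A row of a clonotype table carries an invalid value."""


class ManifestError(ValueError):
    """A sample manifest is malformed or inconsistent."""


class DegenerateSampleError(ValueError):
    """An operation requires productive templates and the sample has none."""


TIMEPOINTS = ("pre_tx", "wk2", "m3", "m6", "m12", "rejection")
# Rejection episodes in this cohort occur on average ~4 months post-transplant,
# so "rejection" sorts after the 3-month protocol visit.
TIMEPOINT_ORDER = {"pre_tx": 0, "wk2": 1, "m3": 2, "rejection": 3, "m6": 4, "m12": 5}
COMPARTMENTS = ("pbmc", "mlr_sort", "biopsy", "urine")
SUBSETS = ("bulk", "cd4", "cd8")
INDUCTION_GROUPS = ("campath", "non_campath")
BIOPSY_STATUSES = ("stable", "borderline", "acute_rejection", "none")

_IMMUNOSEQ_COLS = ["rearrangement", "amino_acid", "v_gene", "j_gene", "templates", "frame_type"]
_AIRR_COLS = ["sequence", "junction_aa", "v_call", "j_call", "duplicate_count", "productive"]
_INTERNAL_COLS = ["cdr3_aa", "v_gene", "j_gene", "productive", "templates"]


@dataclass(frozen=True)
class Clonotype:
    """Identity of a single rearranged TCRβ sequence.

    The nucleotide ``rearrangement`` is the unique key; the CDR3 amino-acid
    string, V/J calls and productive flag are annotations carried along.
    """

    rearrangement: str
    cdr3_aa: str = ""
    v_gene: str = ""
    j_gene: str = ""
    productive: bool = True

    def __post_init__(self) -> None:
        if not self.rearrangement:
            raise ValueError("rearrangement must be non-empty")


@dataclass
class RepertoireSample:
    """One sequencing sample: a clone→template-count table plus metadata.

    ``table`` is indexed by the rearrangement nucleotide string with columns
    ``cdr3_aa, v_gene, j_gene, productive, templates``. ``total_templates``
    and all frequencies are computed over productive clones only.
    ``genome_equivalents`` is the number of input nucleated-cell genomes,
    used (when present) to estimate the T-cell fraction of the sample.
    """

    sample_id: str
    table: pd.DataFrame
    subject_id: str = ""
    timepoint: str = ""
    compartment: str = ""
    subset: str = "bulk"
    genome_equivalents: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _INTERNAL_COLS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate rearrangement in sample table: {dup!r}")
        if self.genome_equivalents is not None and self.genome_equivalents <= 0:
            raise ValueError("genome_equivalents must be > 0 when present")

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[str, int],
        *,
        productive: Mapping[str, bool] | None = None,
        **metadata,
    ) -> "RepertoireSample":
        """Build a sample from a plain ``{rearrangement: templates}`` mapping."""
        keys = list(counts)
        prod = [True if productive is None else bool(productive.get(k, True)) for k in keys]
        table = pd.DataFrame(
            {
                "cdr3_aa": "",
                "v_gene": "",
                "j_gene": "",
                "productive": prod,
                "templates": [int(counts[k]) for k in keys],
            },
            index=pd.Index(keys, name="rearrangement"),
        )
        return cls(sample_id=sample_id, table=table, **metadata)

    @property
    def productive_table(self) -> pd.DataFrame:
        return self.table[self.table["productive"]]

    @property
    def counts(self) -> pd.Series:
        """Template counts of productive clones, indexed by rearrangement."""
        return self.productive_table["templates"]

    @property
    def total_templates(self) -> int:
        return int(self.counts.sum())

    @property
    def n_productive_clonotypes(self) -> int:
        return int((self.counts >= 1).sum())

    def frequencies(self) -> pd.Series:
        return clone_frequencies(self)

    def __len__(self) -> int:
        return len(self.table)


def clone_frequencies(sample: RepertoireSample) -> pd.Series:
    """Productive clone frequencies, normalized to the productive total.

    Raises :class:`DegenerateSampleError` when the sample carries no
    productive templates.
    """
    total = sample.total_templates
    if total <= 0:
        raise DegenerateSampleError(
            f"sample {sample.sample_id!r} has no productive templates"
        )
    return sample.counts / total


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _detect_dialect(columns: Iterable[str]) -> str:
    cols = set(columns)
    if set(_IMMUNOSEQ_COLS) <= cols:
        return "immunoseq"
    if set(_AIRR_COLS) <= cols:
        return "airr"
    raise DialectError(
        "columns match neither dialect; expected "
        f"{_IMMUNOSEQ_COLS} (immunoseq) or {_AIRR_COLS} (airr); got {sorted(cols)}"
    )


def _parse_productive_airr(values: pd.Series) -> pd.Series:
    mapping = {"t": True, "true": True, "f": False, "false": False, "1": True, "0": False}
    out = values.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = values[out.isna()].iloc[0]
        raise RecordError(f"unparseable 'productive' value: {bad!r}")
    return out.astype(bool)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "auto",
    *,
    sample_id: str | None = None,
    **metadata,
) -> RepertoireSample:
    """Read a tab-separated clonotype table into a :class:`RepertoireSample`.

    Duplicate rearrangement rows have their template counts summed.
    Non-productive clones are retained, flagged, and excluded from the
    productive total. ``dialect`` may be ``auto`` (header-based detection),
    ``immunoseq`` or ``airr``. Gzip-compressed files are accepted by
    extension.
    """
    path = Path(path)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if df.shape[0] == 0:
        raise RecordError(f"empty clonotype table: {path}")

    found = _detect_dialect(df.columns)
    if dialect != "auto" and dialect != found:
        expected = _IMMUNOSEQ_COLS if dialect == "immunoseq" else _AIRR_COLS
        missing = [c for c in expected if c not in df.columns]
        raise DialectError(
            f"{path}: requested dialect {dialect!r} but missing column(s) {missing}"
        )

    if found == "immunoseq":
        seq = df["rearrangement"]
        cdr3 = df["amino_acid"].fillna("")
        v, j = df["v_gene"].fillna(""), df["j_gene"].fillna("")
        raw_count = df["templates"]
        productive = df["frame_type"].astype(str).str.strip().str.lower().str.startswith("in")
    else:
        seq = df["sequence"]
        cdr3 = df["junction_aa"].fillna("")
        v, j = df["v_call"].fillna(""), df["j_call"].fillna("")
        raw_count = df["duplicate_count"]
        productive = _parse_productive_airr(df["productive"])

    counts = pd.to_numeric(raw_count, errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RecordError(
            f"{path}: invalid template count {raw_count[bad.idxmax()]!r} at line {line}"
        )
    if seq.isna().any() or (seq.str.len() == 0).any():
        raise RecordError(f"{path}: empty rearrangement sequence")

    parsed = pd.DataFrame(
        {
            "cdr3_aa": cdr3.values,
            "v_gene": v.values,
            "j_gene": j.values,
            "productive": productive.values,
            "templates": counts.astype(np.int64).values,
        },
        index=pd.Index(seq.values, name="rearrangement"),
    )
    # merge duplicate rows for the same rearrangement: counts sum, annotations first
    if parsed.index.has_duplicates:
        grouped = parsed.groupby(level=0, sort=False)
        parsed = grouped.first()
        parsed["templates"] = grouped["templates"].sum()

    return RepertoireSample(
        sample_id=sample_id if sample_id is not None else path.name.split(".")[0],
        table=parsed,
        **metadata,
    )


def write_clonotype_table(
    sample: RepertoireSample, path: str | Path, dialect: str = "immunoseq"
) -> None:
    """Write a sample as a tab-separated clonotype table (round-trip safe).

    Refuses to write a sample with an empty clone map.
    """
    if len(sample.table) == 0:
        raise DegenerateSampleError(
            f"refusing to write empty repertoire {sample.sample_id!r}"
        )
    t = sample.table
    if dialect == "immunoseq":
        out = pd.DataFrame(
            {
                "rearrangement": t.index,
                "amino_acid": t["cdr3_aa"].values,
                "v_gene": t["v_gene"].values,
                "j_gene": t["j_gene"].values,
                "templates": t["templates"].values,
                "frame_type": np.where(t["productive"].values, "In", "Out"),
            }
        )
    elif dialect == "airr":
        out = pd.DataFrame(
            {
                "sequence": t.index,
                "junction_aa": t["cdr3_aa"].values,
                "v_call": t["v_gene"].values,
                "j_call": t["j_gene"].values,
                "duplicate_count": t["templates"].values,
                "productive": np.where(t["productive"].values, "T", "F"),
            }
        )
    else:
        raise DialectError(f"unknown output dialect {dialect!r}")
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


_MANIFEST_COLS = [
    "sample_id",
    "path",
    "subject_id",
    "timepoint",
    "compartment",
    "subset",
    "induction_group",
    "biopsy_status",
]


@dataclass
class SampleManifest:
    """A validated table of samples: ids, file paths and study metadata.

    Paths are resolved relative to the manifest's own directory. Encodes the
    per-subject specimen schedule (pre-transplant PBMC and MLR sorts,
    post-transplant blood, biopsy, urine) together with induction-therapy
    and biopsy-status group labels.
    """

    rows: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.rows["subject_id"]))

    def subject_rows(self, subject_id: str) -> pd.DataFrame:
        return self.rows[self.rows["subject_id"] == subject_id]

    def resolve_path(self, sample_id: str) -> Path:
        row = self.rows.set_index("sample_id").loc[sample_id]
        p = Path(row["path"])
        return p if p.is_absolute() else self.base_dir / p

    def load_sample(self, sample_id: str) -> RepertoireSample:
        row = self.rows.set_index("sample_id").loc[sample_id]
        ge = row.get("genome_equivalents")
        ge = int(ge) if ge not in (None, "", "NA") and not pd.isna(ge) else None
        return read_clonotype_table(
            self.resolve_path(sample_id),
            sample_id=sample_id,
            subject_id=row["subject_id"],
            timepoint=row["timepoint"],
            compartment=row["compartment"],
            subset=row["subset"],
            genome_equivalents=ge,
        )

    def iter_samples(self, subject_id: str | None = None) -> Iterator[RepertoireSample]:
        rows = self.rows if subject_id is None else self.subject_rows(subject_id)
        for sid in rows["sample_id"]:
            yield self.load_sample(sid)


def read_manifest(path: str | Path) -> SampleManifest:
    """Read and validate a sample manifest (tab- or comma-separated).

    Checks: required columns, unique sample ids, known metadata labels,
    existence of every referenced clonotype file, and at most one sample per
    (subject, timepoint, compartment, subset) combination.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLS if c not in rows.columns]
    if missing:
        raise ManifestError(f"{path}: manifest missing column(s) {missing}")

    dup = rows["sample_id"][rows["sample_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate sample_id in manifest: {dup.iloc[0]!r}")
    for col, allowed in [
        ("timepoint", TIMEPOINTS),
        ("compartment", COMPARTMENTS),
        ("subset", SUBSETS),
        ("induction_group", INDUCTION_GROUPS),
        ("biopsy_status", BIOPSY_STATUSES),
    ]:
        bad = rows[col][~rows[col].isin(allowed)]
        if len(bad):
            raise ManifestError(
                f"unknown {col} label {bad.iloc[0]!r}; allowed: {allowed}"
            )
    combo = rows[["subject_id", "timepoint", "compartment", "subset"]]
    if combo.duplicated().any():
        first = combo[combo.duplicated()].iloc[0].tolist()
        raise ManifestError(f"duplicate (subject,timepoint,compartment,subset): {first}")

    base = path.parent
    for _, row in rows.iterrows():
        p = Path(row["path"])
        full = p if p.is_absolute() else base / p
        if not full.exists():
            raise ManifestError(f"manifest references missing file: {full}")
    return SampleManifest(rows=rows.reset_index(drop=True), base_dir=base)
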