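"""Data model, TSV I/O, and validation for longitudinal count studies.

A study is a feature-by-sample matrix of raw sequencing counts (mRNA exons,
miRNAs, or generic features; IDs are opaque strings and never parsed) plus one
clinical annotation record per sample column: which patient the sample belongs
to, whether it is whole blood or tumor tissue, the clinical phase (pre-surgery,
post-surgery, recurrence), and day offsets relative to surgery and, for
recurrence-phase draws, relative to the recurrence diagnosis.  A recurrence
sample may precede the radiological diagnosis, so its diagnosis-relative day
offset can be negative; phases therefore always come from the metadata and are
never inferred from day offsets.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "sample_id",
    "patient_id",
    "tissue",
    "phase",
    "day_rel_surgery",
    "day_rel_recurrence",
)


class StudyValidationError(ValueError):
    """Raised when counts or metadata violate the study data model."""


class CountParseError(StudyValidationError):
    """Raised when a counts TSV contains a malformed cell."""


class Tissue(str, enum.Enum):
    BLOOD = "blood"
    TUMOR = "tumor"


class Phase(str, enum.Enum):
    PRE_SURGERY = "pre_surgery"
    POST_SURGERY = "post_surgery"
    RECURRENCE = "recurrence"


class FeatureKind(str, enum.Enum):
    MRNA_EXON = "mRNA_exon"
    MIRNA = "miRNA"
    GENERIC = "generic"


@dataclass(frozen=True)
class SampleRecord:
    """Clinical annotation for one sample column.

    ``day_rel_surgery`` is in integer days, negative before surgery.  Tumor
    tissue is resected at surgery and carries phase ``pre_surgery`` by
    convention.  ``day_rel_recurrence`` is required for recurrence-phase
    samples and may be negative (a draw preceding the diagnosis day).
    """

    sample_id: str
    patient_id: str
    tissue: Tissue
    phase: Phase
    day_rel_surgery: int
    day_rel_recurrence: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue", Tissue(self.tissue))
        object.__setattr__(self, "phase", Phase(self.phase))
        if not self.sample_id or not self.patient_id:
            raise StudyValidationError("sample_id and patient_id must be non-empty")
        if self.phase is Phase.RECURRENCE and self.day_rel_recurrence is None:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: recurrence-phase sample needs day_rel_recurrence"
            )
        if self.tissue is Tissue.TUMOR and self.phase is not Phase.PRE_SURGERY:
            raise StudyValidationError(
                f"sample {self.sample_id!r}: tumor-tissue samples carry phase pre_surgery"
            )
        if self.tissue is Tissue.BLOOD:
            if self.phase is Phase.PRE_SURGERY and self.day_rel_surgery > 0:
                raise StudyValidationError(
                    f"sample {self.sample_id!r}: pre-surgery blood sample with day_rel_surgery > 0"
                )
            if self.phase is Phase.POST_SURGERY and self.day_rel_surgery <= 0:
                raise StudyValidationError(
                    f"sample {self.sample_id!r}: post-surgery blood sample with day_rel_surgery <= 0"
                )

    @property
    def is_blood(self) -> bool:
        return self.tissue is Tissue.BLOOD


@dataclass
class CountMatrix:
    """Raw counts, features x samples, backed by an integer DataFrame."""

    values: pd.DataFrame
    kind: FeatureKind = FeatureKind.GENERIC

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise StudyValidationError(f"duplicate feature IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise StudyValidationError(f"duplicate sample IDs: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise StudyValidationError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise StudyValidationError(
                f"negative count at feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values[list(sample_ids)], self.kind)


@dataclass
class StudyTable:
    """A validated count matrix with its aligned sample annotations."""

    matrix: CountMatrix
    samples: list[SampleRecord] = field(default_factory=list)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.samples:
            seen.setdefault(rec.patient_id, None)
        return list(seen)

    def samples_for(self, patient_id: str) -> list[SampleRecord]:
        return [r for r in self.samples if r.patient_id == patient_id]

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.samples:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def patient_matrix(self, patient_id: str) -> CountMatrix:
        """All of one patient's columns (blood and tumor), in study order."""
        ids = [r.sample_id for r in self.samples_for(patient_id)]
        return self.matrix.subset_samples(ids)


def read_counts(path: str | Path, kind: FeatureKind | str = FeatureKind.GENERIC) -> CountMatrix:
    """Read a counts TSV (header = sample IDs, first column = feature IDs)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise StudyValidationError(f"duplicate sample IDs in header of {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.columns = sample_ids
    df.index = df.index.astype(str)
    df.index.name = None
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric % 1 != 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise CountParseError(
            f"non-integer count {df.iat[i, j]!r} at feature {df.index[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    neg = numeric < 0
    if neg.to_numpy().any():
        i, j = np.argwhere(neg.to_numpy())[0]
        raise CountParseError(
            f"negative count {df.iat[i, j]!r} at feature {df.index[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return CountMatrix(numeric.astype(np.int64), kind)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read a sample-metadata TSV with the six canonical columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise StudyValidationError(f"metadata missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            tissue = Tissue(row["tissue"])
            phase = Phase(row["phase"])
        except ValueError as exc:
            raise StudyValidationError(
                f"sample {row['sample_id']!r}: unknown tissue/phase token ({exc})"
            ) from None
        drr = row["day_rel_recurrence"].strip()
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                tissue=tissue,
                phase=phase,
                day_rel_surgery=int(row["day_rel_surgery"]),
                day_rel_recurrence=int(drr) if drr != "" else None,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise StudyValidationError(f"duplicate sample IDs in metadata: {dups}")
    return records


def write_metadata(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in samples:
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "tissue": r.tissue.value,
                "phase": r.phase.value,
                "day_rel_surgery": r.day_rel_surgery,
                "day_rel_recurrence": "" if r.day_rel_recurrence is None else r.day_rel_recurrence,
            }
        )
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def validate_study(matrix: CountMatrix, samples: Sequence[SampleRecord]) -> StudyTable:
    """Check per-patient study composition and align metadata to the matrix.

    Every patient must contribute at least one pre-surgery and one post-surgery
    blood sample (the filter cascade is undefined otherwise) and at most one
    tumor-tissue sample.  The returned table's records are reordered to match
    the matrix columns, so the result is independent of input ordering.
    """
    by_id = {r.sample_id: r for r in samples}
    if len(by_id) != len(samples):
        raise StudyValidationError("duplicate sample IDs in metadata")
    missing = [s for s in matrix.sample_ids if s not in by_id]
    if missing:
        raise StudyValidationError(f"samples in matrix missing from metadata: {missing}")
    extra = [s for s in by_id if s not in set(matrix.sample_ids)]
    if extra:
        raise StudyValidationError(f"samples in metadata missing from matrix: {sorted(extra)}")

    ordered = [by_id[s] for s in matrix.sample_ids]
    per_patient: dict[str, list[SampleRecord]] = {}
    for rec in ordered:
        per_patient.setdefault(rec.patient_id, []).append(rec)
    for pid, recs in per_patient.items():
        n_pre = sum(1 for r in recs if r.is_blood and r.phase is Phase.PRE_SURGERY)
        n_post = sum(1 for r in recs if r.is_blood and r.phase is Phase.POST_SURGERY)
        n_rec = sum(1 for r in recs if r.is_blood and r.phase is Phase.RECURRENCE)
        n_tumor = sum(1 for r in recs if r.tissue is Tissue.TUMOR)
        if n_pre == 0:
            raise StudyValidationError(f"patient {pid!r} has no pre-surgery blood sample")
        if n_post == 0:
            raise StudyValidationError(f"patient {pid!r} has no post-surgery blood sample")
        if n_tumor > 1:
            raise StudyValidationError(f"patient {pid!r} has {n_tumor} tumor-tissue samples")
        log.info(
            "patient %s: %d pre-surgery, %d post-surgery, %d recurrence blood sample(s), %d tumor",
            pid, n_pre, n_post, n_rec, n_tumor,
        )
    return StudyTable(matrix=matrix, samples=ordered)


__all__ = [
    "CountMatrix",
    "CountParseError",
    "FeatureKind",
    "METADATA_COLUMNS",
    "Phase",
    "SampleRecord",
    "StudyTable",
    "StudyValidationError",
    "Tissue",
    "read_counts",
    "read_metadata",
    "validate_study",
    "write_counts",
    "write_metadata",
]
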