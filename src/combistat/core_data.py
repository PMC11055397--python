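"""Data model and CSV I/O for protein expression matrices and sample metadata.

The central object is :class:`ExpressionMatrix` — a proteins × samples table of
abundances with an explicit missing mask (NaN) and a ``scale_tag`` recording
whether values are raw intensities or log2/log10 transformed.  Every
preprocessing, imputation and testing stage consumes and returns this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"
LOG10 = "log10"
_SCALE_TAGS = (RAW, LOG2, LOG10)

_NA_STRINGS = {"", "NA", "NaN", "nan", "na", "N/A", "NAN"}


class CombistatError(ValueError):
    """Base class for user-facing validation errors."""


@dataclass
class ExpressionMatrix:
    """Proteins × samples abundance table with an explicit missing mask.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein identifiers, one column per
        sample; ``NaN`` marks a missing measurement.
    scale_tag
        One of ``"raw"``, ``"log2"``, ``"log10"`` — the current transform
        state.  Only the transform operations change it.
    """

    data: pd.DataFrame
    scale_tag: str = RAW

    def __post_init__(self) -> None:
        if self.scale_tag not in _SCALE_TAGS:
            raise CombistatError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {_SCALE_TAGS}"
            )
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise CombistatError(f"duplicate protein ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = sorted(self.data.columns[self.data.columns.duplicated()].unique())
            raise CombistatError(f"duplicate sample ids: {dups}")
        if len(idx) == 0 or len(self.data.columns) == 0:
            raise CombistatError("expression matrix must have >=1 protein and >=1 sample")
        self.data = self.data.astype(float)

    # -- accessors -----------------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Proteins × samples float array; NaN where missing."""
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix with the same orderings and new values."""
        df = pd.DataFrame(np.asarray(values, dtype=float),
                          index=self.data.index.copy(),
                          columns=self.data.columns.copy())
        return ExpressionMatrix(df, scale_tag or self.scale_tag)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), self.scale_tag)


@dataclass(frozen=True)
class SampleMetadata:
    """One record per sample: class label plus optional batch / reference flag."""

    sample_id: str
    class_label: str
    batch: str | None = None
    is_reference: bool = False


@dataclass(frozen=True)
class ClassSet:
    """Deterministically (lexicographically) ordered set of class labels."""

    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise CombistatError("ClassSet labels must be distinct")
        if list(self.classes) != sorted(self.classes):
            object.__setattr__(self, "classes", tuple(sorted(self.classes)))

    @property
    def n(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __contains__(self, label: str) -> bool:
        return label in self.classes


class MetadataTable:
    """Collection of :class:`SampleMetadata` records with lookup helpers."""

    def __init__(self, records: Sequence[SampleMetadata]):
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            dups = sorted({s for s in ids if ids.count(s) > 1})
            raise CombistatError(f"duplicate sample ids in metadata: {dups}")
        self.records = list(records)
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def class_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].class_label

    def class_set(self) -> ClassSet:
        return ClassSet(tuple(sorted({r.class_label for r in self.records})))

    def samples_in_classes(self, classes: Iterable[str]) -> list[str]:
        wanted = set(classes)
        return [r.sample_id for r in self.records if r.class_label in wanted]

    def batches(self) -> list[str]:
        return sorted({r.batch for r in self.records if r.batch is not None})

    def samples_in_batch(self, batch: str) -> list[str]:
        return [r.sample_id for r in self.records if r.batch == batch]

    def reference_samples(self, batch: str) -> list[str]:
        return [r.sample_id for r in self.records
                if r.batch == batch and r.is_reference]

    def require_two_classes(self) -> None:
        if self.class_set().n < 2:
            raise CombistatError(
                "differential analysis needs >=2 distinct class labels; "
                f"found {self.class_set().classes}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": [r.sample_id for r in self.records],
                "class": [r.class_label for r in self.records],
                "batch": [r.batch for r in self.records],
                "reference": [r.is_reference for r in self.records],
            }
        )


# -- CSV I/O -----------------------------------------------------------------

def read_expression_csv(
    path: str | Path,
    id_column: str | None = None,
    *,
    zero_as_missing: bool = False,
    transpose: bool = False,
    scale_tag: str = RAW,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV.

    The first column (or ``id_column``) holds unique protein identifiers; the
    remaining columns are samples.  Empty cells and the literal strings
    "NA"/"NaN" become missing; zeros become missing only when
    ``zero_as_missing`` is set (label-free exports often encode missingness
    as 0).  ``transpose`` accepts the samples-as-rows dialect.
    """
    path = Path(path)
    if not path.exists():
        raise CombistatError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise CombistatError("expression CSV needs an id column plus >=1 sample column")
    if id_column is None:
        id_column = raw.columns[0]
    if id_column not in raw.columns:
        raise CombistatError(f"id column {id_column!r} not found in {list(raw.columns)}")
    ids = raw[id_column].str.strip()
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise CombistatError(f"duplicate protein ids: {sorted(dup.unique().tolist())}")
    body = raw.drop(columns=[id_column])

    def _parse(cell: str, row: str, col: str) -> float:
        cell = cell.strip()
        if cell in _NA_STRINGS:
            return np.nan
        try:
            v = float(cell)
        except ValueError:
            raise CombistatError(
                f"non-numeric value {cell!r} at protein {row!r}, sample {col!r}"
            ) from None
        return v

    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        column = body[col].to_numpy()
        for i, cell in enumerate(column):
            values[i, j] = _parse(cell, ids.iloc[i], col)
    if zero_as_missing:
        values[values == 0.0] = np.nan
    df = pd.DataFrame(values, index=ids.tolist(), columns=body.columns.tolist())
    if transpose:
        df = df.T
    return ExpressionMatrix(df, scale_tag)


def write_expression_csv(matrix: ExpressionMatrix, path: str | Path,
                         id_column: str = "protein") -> None:
    """Write a matrix to CSV (missing cells become empty fields)."""
    df = matrix.data.copy()
    df.index.name = id_column
    df.to_csv(path, na_rep="")


def read_metadata_csv(path: str | Path) -> MetadataTable:
    """Read sample metadata: columns ``sample``, ``class``, optional
    ``batch`` and ``reference``."""
    path = Path(path)
    if not path.exists():
        raise CombistatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("sample", "class"):
        if col not in df.columns:
            raise CombistatError(f"metadata CSV must have a {col!r} column")
    records = []
    for _, row in df.iterrows():
        batch = row.get("batch", "")
        batch = batch.strip() if isinstance(batch, str) else ""
        ref = str(row.get("reference", "")).strip().lower() in {"1", "true", "yes", "y"}
        records.append(SampleMetadata(
            sample_id=row["sample"].strip(),
            class_label=row["class"].strip(),
            batch=batch or None,
            is_reference=ref,
        ))
    meta = MetadataTable(records)
    # iRS sanity: a flagged reference implies every batch has one
    if any(r.is_reference for r in meta.records):
        for b in meta.batches():
            if not meta.reference_samples(b):
                raise CombistatError(f"batch {b!r} has no reference sample")
    return meta


def write_metadata_csv(meta: MetadataTable, path: str | Path) -> None:
    meta.to_frame().to_csv(path, index=False)


def align_metadata(matrix: ExpressionMatrix, meta: MetadataTable) -> MetadataTable:
    """Check every matrix sample has metadata; return metadata restricted to
    and ordered like the matrix columns."""
    missing = [s for s in matrix.sample_ids if s not in meta._by_id]
    if missing:
        raise CombistatError(f"samples missing from metadata: {missing}")
    return MetadataTable([meta[s] for s in matrix.sample_ids])


# -- validation --------------------------------------------------------------

@dataclass
class ValidationReport:
    per_sample_missing_fraction: pd.Series
    per_class_sample_counts: pd.Series
    all_missing_proteins: list[str]
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"missing_fraction": self.per_sample_missing_fraction})


def validate(matrix: ExpressionMatrix, meta: MetadataTable) -> ValidationReport:
    """Report per-sample missingness, class sizes and degenerate proteins.

    Purely diagnostic: never raises, never mutates its inputs.
    """
    meta = align_metadata(matrix, meta)
    mask = matrix.missing_mask
    frac = pd.Series(mask.mean(axis=0), index=matrix.sample_ids, name="missing_fraction")
    classes = pd.Series([meta.class_of(s) for s in matrix.sample_ids])
    counts = classes.value_counts().sort_index()
    counts.name = "n_samples"
    all_missing = [pid for pid, row in zip(matrix.protein_ids, mask) if row.all()]
    warnings = []
    for pid in all_missing:
        warnings.append(f"protein {pid!r} has no observed values")
    for cls, n in counts.items():
        if n < 2:
            warnings.append(
                f"class {cls!r} has {n} replicate(s); variance estimation "
                "needs >=2 replicates per group"
            )
    return ValidationReport(frac, counts, all_missing, warnings)
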