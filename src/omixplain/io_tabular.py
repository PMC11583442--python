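"""Tabular I/O: the samples × features table, targets, and output writing.

The pipeline's universal currency is the :class:`FeatureTable` — a numeric
matrix with unique sample identifiers on the rows and unique feature
identifiers on the columns.  Input files are plain CSV, samples in rows,
header row of feature names, first column of sample IDs.  Transposed input
is an error, never auto-detected: silent transposition is a classic omics
bug.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class TableError(ValueError):
    """Raised for malformed or inconsistent tabular inputs."""


@dataclass
class FeatureTable:
    """Samples × features numeric matrix with identifiers.

    ``data`` is a pandas DataFrame whose index holds sample IDs and whose
    columns hold feature IDs.  All values must be finite; missing entries
    are an error, not silently imputed.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index.astype(str)
        cols = self.data.columns.astype(str)
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise TableError(f"duplicate feature IDs: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.data)
            raise TableError(f"non-numeric value at {bad}")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise TableError(
                f"non-finite value at sample {idx[r]!r}, feature {cols[c]!r}"
            )
        self.data = self.data.copy()
        self.data.index = idx
        self.data.columns = cols

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(ids)])

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(ids)])


@dataclass
class TargetVector:
    """Per-sample label (classification) or numeric value (regression)."""

    series: pd.Series
    kind: str  # "class" | "numeric"

    def __post_init__(self) -> None:
        if self.kind not in ("class", "numeric"):
            raise TableError(f"unknown target kind {self.kind!r}")
        s = self.series.copy()
        s.index = s.index.astype(str)
        if s.index.has_duplicates:
            raise TableError("duplicate sample IDs in target")
        if s.isna().any():
            missing = s.index[s.isna()].tolist()
            raise TableError(f"missing target values for samples {missing}")
        if self.kind == "numeric":
            s = pd.to_numeric(s)
        else:
            s = s.astype(str)
            if s.nunique() < 2:
                raise TableError("classification target needs >= 2 classes")
        self.series = s

    @property
    def sample_ids(self) -> list[str]:
        return self.series.index.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.series.to_numpy()

    def classes(self) -> list[str]:
        if self.kind != "class":
            raise TableError("classes() on a numeric target")
        return sorted(self.series.unique().tolist())

    def subset(self, ids: Sequence[str]) -> "TargetVector":
        return TargetVector(self.series.loc[list(ids)], self.kind)


def _first_non_numeric(df: pd.DataFrame) -> str:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            return f"sample {row!r}, feature {col!r} (value {df.loc[row, col]!r})"
    return "unknown cell"


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a samples × features CSV (first column sample IDs, header row)."""
    df = pd.read_csv(path, index_col=0)
    if df.isna().any().any():
        mask = df.isna()
        col = mask.any(axis=0).idxmax()
        row = df.index[mask[col].argmax()]
        raise TableError(
            f"missing/NA value at sample {row!r}, feature {col!r} in {path}"
        )
    obj_cols = df.columns[df.dtypes == object]
    if len(obj_cols):
        bad = _first_non_numeric(df[list(obj_cols)])
        raise TableError(f"non-numeric value at {bad} in {path}")
    return FeatureTable(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the metadata CSV (first column sample IDs)."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise TableError(f"duplicate sample IDs in metadata {path}")
    return meta


def target_from_metadata(
    meta: pd.DataFrame, column: str, kind: str
) -> TargetVector:
    if column not in meta.columns:
        raise TableError(
            f"target column {column!r} absent from metadata "
            f"(available: {list(meta.columns)})"
        )
    return TargetVector(meta[column], kind)


def align(
    table: FeatureTable, target: TargetVector
) -> tuple[FeatureTable, TargetVector]:
    """Restrict table and target to their common samples, in table order.

    Idempotent; the number of dropped samples is logged.
    """
    common = [s for s in table.sample_ids if s in set(target.sample_ids)]
    if not common:
        raise TableError("no samples in common between data and metadata")
    dropped = (len(table.sample_ids) - len(common)) + (
        len(target.sample_ids) - len(common)
    )
    if dropped:
        logger.info("align: dropped %d unmatched samples", dropped)
    return table.subset_samples(common), target.subset(common)


#: call-token → dosage, following the convention that the code grows with
#: the count of alternate alleles (hom-ref 0, het 1, hom-alt 2, missing 3).
GENOTYPE_CODES: Mapping[str, int] = {
    "hom_ref": 0,
    "het": 1,
    "hom_alt": 2,
    "NN": 3,
}


def encode_genotypes(
    calls: pd.DataFrame, invert: bool = False
) -> FeatureTable:
    """Encode categorical genotype calls as 0/1/2 dosages (3 = missing).

    ``invert=True`` flips to ref=2 … alt=0 (some published matrices count
    reference rather than alternate alleles).
    """
    codes = dict(GENOTYPE_CODES)
    if invert:
        codes["hom_ref"], codes["hom_alt"] = codes["hom_alt"], codes["hom_ref"]
    known = set(codes)
    flat = pd.unique(calls.to_numpy().ravel())
    unknown = [tok for tok in flat if tok not in known]
    if unknown:
        raise TableError(
            f"unrecognized genotype tokens {unknown[:5]}; expected {sorted(known)}"
        )
    encoded = calls.apply(lambda col: col.map(codes)).astype(int)
    return FeatureTable(encoded)


def write_results_table(results: pd.DataFrame, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "results.csv"
    results.to_csv(path, index=False)
    return path


def write_outputs(
    results: pd.DataFrame,
    explanation_files: Iterable[Path],
    best_model_name: str,
    best_model_files: Iterable[Path],
    out_dir: str | Path,
    tie_note: str | None = None,
) -> list[Path]:
    """Write the results table, copy best-model artifacts, emit a tie note.

    The explanation CSVs are produced by :mod:`omixplain.explain` with their
    fixed name templates and are listed here only for the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = [write_results_table(results, out_dir)]
    best_dir = out_dir / "best_model"
    best_dir.mkdir(exist_ok=True)
    (best_dir / "model_name.txt").write_text(best_model_name + "\n")
    written.append(best_dir / "model_name.txt")
    for f in best_model_files:
        f = Path(f)
        if f.exists():
            dest = best_dir / f.name
            shutil.copy(f, dest)
            written.append(dest)
    if tie_note is not None:
        note = out_dir / "best_model_tie_note.txt"
        note.write_text(tie_note + "\n")
        written.append(note)
    written.extend(Path(f) for f in explanation_files)
    return written
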