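"""Feature tables, per-sample metadata, and per-subject trajectories.

This module handles the plumbing that precedes any temporal analysis:
reading sample-by-feature relative-abundance tables (TSV, or BIOM v2.1
HDF5), joining them with per-sample metadata (subject id, age in days,
phenotype labels), removing rare features, assembling each subject's
chronologically ordered trajectory, and trimming trajectory pairs to their
shared time points.

Conventions
-----------
* Feature tables are samples x features; rows are re-normalized to relative
  abundances (fractions summing to 1) on load.
* Metadata TSVs require the columns ``sample_id``, ``subject_id`` and
  ``age_days``; any further columns become phenotype labels.
* Ages are in days since birth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("trajalign")

#: tolerance on compositional row sums
ROW_SUM_TOL = 1e-8

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "age_days")


class ValidationError(ValueError):
    """Raised when an input violates a structural contract."""


def _normalize_rows(matrix: np.ndarray, what: str, ids) -> np.ndarray:
    sums = matrix.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [str(ids[i]) for i in np.flatnonzero(zero)[:5]]
        raise ValidationError(
            f"{what}: rows with zero total abundance cannot be normalized "
            f"(e.g. {', '.join(bad)})"
        )
    return matrix / sums[:, None]


@dataclass
class FeatureTable:
    """Samples-by-features matrix of relative abundances.

    Rows are samples, columns features; every entry lies in [0, 1] and each
    row sums to 1 within :data:`ROW_SUM_TOL`.
    """

    sample_ids: list
    feature_ids: list
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.feature_ids = list(self.feature_ids)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id in feature table")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature_id in feature table")
        if not np.isfinite(self.abundances).all():
            raise ValidationError("feature table contains non-finite values")
        if (self.abundances < 0).any() or (self.abundances > 1 + ROW_SUM_TOL).any():
            raise ValidationError("abundances must lie in [0, 1]")
        if np.abs(self.abundances.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
            raise ValidationError("feature table rows must sum to 1")

    @classmethod
    def from_counts(cls, sample_ids, feature_ids, counts) -> "FeatureTable":
        """Build a table from raw (non-negative) counts, normalizing each row."""
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        return cls(sample_ids, feature_ids, _normalize_rows(counts, "from_counts", sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundances, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class SampleMetadata:
    """Per-sample annotations: owning subject, age, phenotype labels."""

    sample_id: str
    subject_id: str
    age_days: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_days = float(self.age_days)
        if not np.isfinite(self.age_days) or self.age_days < 0:
            raise ValidationError(f"sample {self.sample_id}: age_days must be >= 0")


@dataclass
class Trajectory:
    """One subject's chronologically ordered compositional samples."""

    subject_id: str
    times: np.ndarray
    samples: np.ndarray
    feature_ids: list

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        self.feature_ids = list(self.feature_ids)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValidationError(f"{self.subject_id}: trajectory needs >= 1 sample")
        if self.samples.shape != (len(self.times), len(self.feature_ids)):
            raise ValidationError(f"{self.subject_id}: samples shape mismatch")
        diffs = np.diff(self.times)
        if (diffs < 0).any():
            raise ValidationError(f"{self.subject_id}: times must be non-decreasing")
        if (diffs == 0).any():
            # equal-age samples are kept (deterministically ordered upstream)
            logger.warning("subject %s has samples at identical ages", self.subject_id)
        if (self.samples < 0).any():
            raise ValidationError(f"{self.subject_id}: negative abundance")
        if np.abs(self.samples.sum(axis=1) - 1.0).max() > ROW_SUM_TOL:
            raise ValidationError(f"{self.subject_id}: sample rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def subset(self, idx, subject_id: str | None = None) -> "Trajectory":
        """Row subset (chronological order preserved by the caller's index)."""
        idx = np.asarray(idx)
        return Trajectory(
            subject_id if subject_id is not None else self.subject_id,
            self.times[idx],
            self.samples[idx],
            self.feature_ids,
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_tsv_table(table_path) -> pd.DataFrame:
    df = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate sample_id {dup!r} in {table_path}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"malformed numeric cell at row {row!r}, column {col!r} in {table_path}"
            )
        numeric[col] = vals
    if numeric.isna().any().any():
        raise ValidationError(f"missing values in {table_path}")
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"negative abundance in {table_path}")
    return numeric


def _read_biom_table(table_path) -> pd.DataFrame:
    """Minimal BIOM v2.1 (HDF5) reader: returns a samples x features frame."""
    import h5py

    with h5py.File(table_path, "r") as fh:
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample/ids"][:]]
        feature_ids = [
            s.decode() if isinstance(s, bytes) else str(s) for s in fh["observation/ids"][:]
        ]
        data = fh["sample/matrix/data"][:]
        indices = fh["sample/matrix/indices"][:]
        indptr = fh["sample/matrix/indptr"][:]
    dense = np.zeros((len(sample_ids), len(feature_ids)))
    for j in range(len(sample_ids)):
        rows = indices[indptr[j] : indptr[j + 1]]
        dense[j, rows] = data[indptr[j] : indptr[j + 1]]
    if (dense < 0).any():
        raise ValidationError(f"negative abundance in {table_path}")
    return pd.DataFrame(dense, index=sample_ids, columns=feature_ids)


def load_table(table_path, metadata_path) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Load a feature table and its metadata, keeping their common samples.

    The table is TSV (first column ``sample_id``, header of feature ids) or
    BIOM v2.1 HDF5 (detected by a ``.biom`` suffix). Raw values are
    re-normalized per sample to relative abundances. Samples present in only
    one of the two files are dropped with a logged warning.
    """
    if str(table_path).endswith(".biom"):
        df = _read_biom_table(table_path)
    else:
        df = _read_tsv_table(table_path)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing required columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r} in metadata")

    table_samples = set(df.index)
    meta_samples = set(meta["sample_id"])
    only_table = sorted(table_samples - meta_samples)
    only_meta = sorted(meta_samples - table_samples)
    if only_table:
        logger.warning("%d table samples missing from metadata; dropped", len(only_table))
    if only_meta:
        logger.warning("%d metadata rows missing from table; dropped", len(only_meta))
    common = [s for s in df.index if s in meta_samples]
    if not common:
        raise ValidationError("no samples shared between table and metadata")
    df = df.loc[common]

    table = FeatureTable.from_counts(list(df.index), list(df.columns), df.to_numpy())
    label_cols = [c for c in meta.columns if c not in REQUIRED_METADATA_COLUMNS]
    meta = meta.set_index("sample_id").loc[common]
    records = [
        SampleMetadata(
            sample_id=sid,
            subject_id=row["subject_id"],
            age_days=float(row["age_days"]),
            labels={c: row[c] for c in label_cols if pd.notna(row[c])},
        )
        for sid, row in meta.iterrows()
    ]
    return table, records


def write_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV (samples x features)."""
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    rows = []
    for m in metadata:
        row = {"sample_id": m.sample_id, "subject_id": m.subject_id, "age_days": m.age_days}
        row.update(m.labels)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and trajectory assembly
# ---------------------------------------------------------------------------

def filter_rare_features(
    table: FeatureTable, threshold: float = 0.001, min_samples: int = 2
) -> FeatureTable:
    """Drop features not exceeding ``threshold`` relative abundance in at
    least ``min_samples`` samples; remaining rows are re-normalized.

    The comparison is strict (abundance must be > threshold), applied to the
    relative abundances of the full dataset, and feature order is preserved.
    The operation is idempotent: re-normalization can only increase the
    relative abundance of the retained features.
    """
    keep = (table.abundances > threshold).sum(axis=0) >= min_samples
    if not keep.any():
        raise ValidationError(
            f"rare-feature filter removed all features; lower threshold "
            f"(currently {threshold}) or min_samples (currently {min_samples})"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("rare-feature filter removed %d of %d features", n_removed, keep.size)
    sub = table.abundances[:, keep]
    sums = sub.sum(axis=1)
    dead = sums <= 0
    sample_ids = table.sample_ids
    if dead.any():
        logger.warning(
            "%d samples carried only rare features and were dropped", int(dead.sum())
        )
        sub = sub[~dead]
        sample_ids = [s for s, d in zip(sample_ids, dead) if not d]
    feature_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    return FeatureTable.from_counts(sample_ids, feature_ids, sub)


def build_trajectories(
    table: FeatureTable, metadata: list[SampleMetadata]
) -> list[Trajectory]:
    """Assemble one chronologically sorted :class:`Trajectory` per subject.

    Samples are sorted by ``age_days``; ties are broken by lexical
    ``sample_id`` order (logged) so pipelines are reproducible. Subjects
    with no samples in the table are omitted with a warning. Trajectories
    are returned sorted by subject id.
    """
    pos = {sid: i for i, sid in enumerate(table.sample_ids)}
    by_subject: dict[str, list[SampleMetadata]] = {}
    for m in metadata:
        by_subject.setdefault(m.subject_id, []).append(m)

    out = []
    for subject_id in sorted(by_subject):
        records = [m for m in by_subject[subject_id] if m.sample_id in pos]
        if not records:
            logger.warning("subject %s has no samples in the table; omitted", subject_id)
            continue
        records.sort(key=lambda m: (m.age_days, m.sample_id))
        ages = [m.age_days for m in records]
        if len(set(ages)) != len(ages):
            logger.warning(
                "subject %s: age ties broken by sample_id order", subject_id
            )
        idx = [pos[m.sample_id] for m in records]
        out.append(
            Trajectory(subject_id, ages, table.abundances[idx], table.feature_ids)
        )
    return out


def trim_to_overlap(a: Trajectory, b: Trajectory) -> tuple[Trajectory, Trajectory]:
    """Restrict both trajectories to time points present in both.

    Intended for trajectories interpolated onto the shared grid convention
    (multiples of the interpolation interval), where exact time equality is
    meaningful.
    """
    shared = np.intersect1d(a.times, b.times)
    if shared.size == 0:
        raise ValidationError(
            f"no shared time points between {a.subject_id} and {b.subject_id}"
        )
    ia = np.flatnonzero(np.isin(a.times, shared))
    ib = np.flatnonzero(np.isin(b.times, shared))
    return a.subset(ia), b.subset(ib)
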