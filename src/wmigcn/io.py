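"""Reading and writing ECG records, adjacency matrices and dataset manifests.

The on-disk dialect is deliberately plain: one CSV per record holding the
12-lead signal matrix (columns or rows per lead, optional header of lead
names), a label table CSV with ``record_id,label`` columns, and lead-labelled
CSVs for 12x12 matrices.  The same dialect is used for synthetic and real
data, so the two are interchangeable downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical 12-lead order used for every matrix index in the package.
LEAD_ORDER: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = len(LEAD_ORDER)


class ECGParseError(ValueError):
    """A cell in a record file could not be parsed as a number."""


class ShapeError(ValueError):
    """A record file does not contain exactly 12 lead series."""


class ValidationError(ValueError):
    """A loaded object violates a structural invariant (e.g. NaN samples)."""


@dataclass
class ECGRecord:
    """One subject's 12-lead ECG.

    ``signal`` is a ``(12, T)`` float array in millivolt scale, rows in the
    order given by ``leads`` (canonical order after loading).
    """

    record_id: str
    signal: np.ndarray
    leads: tuple[str, ...] = LEAD_ORDER
    sampling_rate_hz: float = 500.0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise ShapeError(
                f"record {self.record_id!r}: expected a (12, T) signal, "
                f"got shape {self.signal.shape}"
            )
        if self.signal.shape[1] < 2:
            raise ValidationError(
                f"record {self.record_id!r}: need at least 2 samples per lead"
            )
        if sorted(self.leads) != sorted(LEAD_ORDER):
            raise ValidationError(
                f"record {self.record_id!r}: lead names must be a permutation "
                f"of the standard 12, got {self.leads}"
            )
        if not np.isfinite(self.signal).all():
            raise ValidationError(
                f"record {self.record_id!r}: signal contains non-finite values"
            )
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        self.leads = tuple(self.leads)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def reordered(self) -> "ECGRecord":
        """Return a copy with rows in the canonical lead order."""
        if self.leads == LEAD_ORDER:
            return self
        idx = [self.leads.index(name) for name in LEAD_ORDER]
        return ECGRecord(
            record_id=self.record_id,
            signal=self.signal[idx],
            leads=LEAD_ORDER,
            sampling_rate_hz=self.sampling_rate_hz,
            label=self.label,
        )


@dataclass
class DatasetManifest:
    """Index of a labelled record collection: (record_id, path, label) rows."""

    records: list[tuple[str, Optional[str], str]]
    class_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_counts:
            counts: dict[str, int] = {}
            for _, _, label in self.records:
                counts[label] = counts.get(label, 0) + 1
            self.class_counts = counts
        for _, _, label in self.records:
            if not label:
                raise ValidationError("every record needs a non-empty label")
        if sum(self.class_counts.values()) != len(self.records):
            raise ValidationError("class_counts must sum to the record count")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [rid for rid, _, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [label for _, _, label in self.records]


def _read_numeric_table(path: str | os.PathLike) -> np.ndarray:
    """Read a CSV of floats, tolerating an optional single header row."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",")]

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(t) for t in tokens if t != "")
    try:
        frame = pd.read_csv(path, header=0 if has_header else None)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ECGParseError(f"{path}: {exc}") from exc
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ECGParseError(
                f"{path}: non-numeric cell at row {row}, column {col!r}"
            )
        frame[col] = coerced
    values = frame.to_numpy(dtype=float)
    header = [str(c) for c in frame.columns] if has_header else None
    return values, header


def read_record(
    path: str | os.PathLike,
    lead_order: Optional[Sequence[str]] = None,
    fs: float = 500.0,
    record_id: Optional[str] = None,
) -> ECGRecord:
    """Load a per-record CSV into an :class:`ECGRecord`.

    The table may hold leads as columns (``T x 12``, preferred when ambiguous)
    or as rows (``12 x T``); orientation is auto-detected from the shape.  If
    the file carries a header of lead names those name the columns; otherwise
    ``lead_order`` (default: canonical) assigns names.  Rows are reordered to
    the canonical order I, II, III, aVR, aVL, aVF, V1..V6.
    """
    path = Path(path)
    values, header = _read_numeric_table(path)
    if values.ndim != 2:
        raise ShapeError(f"{path}: expected a 2-D table")

    n_rows, n_cols = values.shape
    if n_cols == N_LEADS:
        # columns-as-leads preferred whenever there are exactly 12 columns
        signal = values.T
        names = header if header is not None else list(lead_order or LEAD_ORDER)
    elif n_rows == N_LEADS:
        signal = values
        names = list(lead_order or LEAD_ORDER)
    else:
        raise ShapeError(
            f"{path}: expected 12 lead series, got shape {values.shape}"
        )
    if len(names) != N_LEADS or sorted(names) != sorted(LEAD_ORDER):
        # header present but not lead names -> fall back to declared order
        names = list(lead_order or LEAD_ORDER)
    rec = ECGRecord(
        record_id=record_id or path.stem,
        signal=signal,
        leads=tuple(names),
        sampling_rate_hz=fs,
    )
    return rec.reordered()


def write_record(rec: ECGRecord, path: str | os.PathLike) -> None:
    """Write a record in the columns-as-leads CSV dialect with a header."""
    rec = rec.reordered()
    frame = pd.DataFrame(rec.signal.T, columns=list(rec.leads))
    frame.to_csv(path, index=False, float_format="%.10g")


def write_matrix(m: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 12x12 matrix as a CSV with lead-name header row and column."""
    m = np.asarray(m, dtype=float)
    if m.shape != (N_LEADS, N_LEADS):
        raise ShapeError(f"expected a 12x12 matrix, got {m.shape}")
    if not np.isfinite(m).all():
        raise ValidationError("matrix contains non-finite entries")
    frame = pd.DataFrame(m, index=list(LEAD_ORDER), columns=list(LEAD_ORDER))
    frame.to_csv(path, float_format="%.17g")


def read_matrix(path: str | os.PathLike) -> np.ndarray:
    """Read back a matrix written by :func:`write_matrix`."""
    frame = pd.read_csv(path, index_col=0)
    m = frame.to_numpy(dtype=float)
    if m.shape != (N_LEADS, N_LEADS):
        raise ShapeError(f"{path}: expected a 12x12 matrix, got {m.shape}")
    return m


def read_label_table(path: str | os.PathLike) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    if not {"record_id", "label"} <= set(frame.columns):
        raise ValidationError(
            f"{path}: label table needs 'record_id' and 'label' columns"
        )
    return dict(zip(frame["record_id"], frame["label"]))


def scan_dataset(
    directory: str | os.PathLike,
    label_table: str | os.PathLike | Mapping[str, str],
) -> DatasetManifest:
    """Build a manifest of the records present both on disk and in the table."""
    directory = Path(directory)
    labels = (
        dict(label_table)
        if isinstance(label_table, Mapping)
        else read_label_table(label_table)
    )
    rows: list[tuple[str, Optional[str], str]] = []
    for f in sorted(directory.glob("*.csv")):
        rid = f.stem
        if rid in labels:
            rows.append((rid, str(f), labels[rid]))
    if not rows:
        raise ValidationError(
            f"no overlap between records in {directory} and the label table"
        )
    return DatasetManifest(records=rows)


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(manifest.records, columns=["record_id", "path", "label"])
    frame.to_csv(path, index=False)
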