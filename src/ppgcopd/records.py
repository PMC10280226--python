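"""Record data model and cohort I/O.

A :class:`PpgRecord` is one subject's raw photoplethysmogram: the sample
vector, its sampling rate, the binary diagnostic label and optional
demographics (age, weight, height, sex). A :class:`Cohort` is an ordered
collection of records loaded from a manifest CSV.

Signals travel as either two-column CSV (``time,amplitude``; the sampling
rate is recovered from the time grid) or single-channel EDF. Amplitudes are
in arbitrary units throughout: pulse-oximeter hardware is uncalibrated and
every downstream feature is either scale-free or standardized before
classification.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import edf as _edf
from .exceptions import (
    CorruptSignal,
    DuplicateSubject,
    IrregularSampling,
    LabelParseError,
    PpgIoError,
)

COPD = "COPD"
HEALTHY = "HEALTHY"
UNKNOWN = "UNKNOWN"

#: minimum accepted sampling rate: Nyquist must clear the 20 Hz denoise edge
MIN_FS = 50.0


def parse_label(token: str) -> str:
    """Case-insensitive label parse; '1'/'0' accepted as COPD/HEALTHY."""
    t = str(token).strip().upper()
    if t in (COPD, "1", "PATIENT", "SICK"):
        return COPD
    if t in (HEALTHY, "0", "CONTROL"):
        return HEALTHY
    if t in (UNKNOWN, ""):
        return UNKNOWN
    raise LabelParseError(f"unrecognized label token {token!r}")


@dataclass
class PpgRecord:
    subject_id: str
    samples: np.ndarray
    fs: float
    label: str = UNKNOWN
    age: float | None = None
    weight: float | None = None
    height: float | None = None
    sex: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise CorruptSignal(
                f"record {self.subject_id}: non-finite samples")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label not in (COPD, HEALTHY, UNKNOWN):
            self.label = parse_label(self.label)
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "PpgRecord":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class Cohort:
    records: list[PpgRecord]
    manifest: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DuplicateSubject(f"duplicate subject ids: {sorted(dupes)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, subject_id: str) -> PpgRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    return "edf" if suffix == ".edf" else "csv"


def read_record(path, format=None, channel=0, fs=None, subject_id=None,
                label=UNKNOWN, **demographics) -> PpgRecord:
    """Read a signal file into a PpgRecord.

    CSV files need a header row and either columns ``time,amplitude`` (fs is
    the inverted median time step) or a single amplitude column plus an
    explicit *fs*. EDF sampling rate comes from the file header.
    """
    fmt = _infer_format(path, format)
    sid = subject_id if subject_id is not None else Path(path).stem
    if fmt == "edf":
        samples, fs_file, _ = _edf.read_edf(path, channel=channel)
        return PpgRecord(sid, samples, fs_file, label=label, **demographics)
    if fmt != "csv":
        raise PpgIoError(f"unknown record format {fmt!r}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PpgIoError(f"cannot read CSV {path}: {exc}") from exc
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        x = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise PpgIoError(f"{path}: need at least 2 samples for a time grid")
        med = float(np.median(dt))
        if med <= 0 or np.max(np.abs(dt - med)) > 0.01 * med:
            raise IrregularSampling(
                f"{path}: time column is not a uniform grid")
        fs_eff = 1.0 / med
    else:
        if fs is None:
            raise PpgIoError(
                f"{path}: single-column CSV requires an explicit fs")
        x = df.iloc[:, 0].to_numpy(dtype=float)
        fs_eff = float(fs)
    if not np.all(np.isfinite(x)):
        raise CorruptSignal(f"{path}: non-finite samples")
    return PpgRecord(sid, x, fs_eff, label=label, **demographics)


def write_record(record: PpgRecord, path, format=None) -> str:
    """Write a record; CSV is written as time,amplitude at full precision."""
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _edf.write_edf(path, record.samples, record.fs,
                              patient_id=record.subject_id)
    if fmt != "csv":
        raise PpgIoError(f"unknown record format {fmt!r}")
    t = np.arange(record.samples.size) / record.fs
    df = pd.DataFrame({"time": t, "amplitude": record.samples})
    try:
        df.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:
        raise PpgIoError(f"cannot write CSV to {path}: {exc}") from exc
    return os.fspath(path)


MANIFEST_COLUMNS = ("path", "label", "age", "weight", "height", "sex")


def load_cohort(manifest_path) -> Cohort:
    """Load all records listed in a manifest CSV, preserving row order.

    Required columns: ``path`` and ``label``; optional: ``subject_id``
    (default: file stem), ``fs`` (for amplitude-only CSVs), demographics
    ``age, weight, height, sex``. Relative paths resolve against the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    try:
        manifest = pd.read_csv(manifest_path)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise PpgIoError(f"cannot read manifest {manifest_path}: {exc}") from exc
    for col in ("path", "label"):
        if col not in manifest.columns:
            raise PpgIoError(f"manifest lacks required column {col!r}")

    records = []
    for i, row in manifest.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = manifest_path.parent / p
        demo = {}
        for col in ("age", "weight", "height"):
            if col in manifest.columns and pd.notna(row[col]):
                demo[col] = float(row[col])
        if "sex" in manifest.columns and pd.notna(row.get("sex")):
            demo["sex"] = str(row["sex"])
        sid = (str(row["subject_id"])
               if "subject_id" in manifest.columns and pd.notna(row["subject_id"])
               else None)
        fs = (float(row["fs"])
              if "fs" in manifest.columns and pd.notna(row.get("fs"))
              else None)
        try:
            rec = read_record(p, fs=fs, subject_id=sid,
                              label=parse_label(row["label"]), **demo)
        except PpgIoError as exc:
            raise PpgIoError(f"manifest row {i} ({row['path']}): {exc}") from exc
        records.append(rec)
    return Cohort(records, manifest=manifest)


def write_manifest(cohort: Cohort, paths: Sequence[str], out_path) -> str:
    """Write a manifest CSV for records stored at *paths* (same order)."""
    rows = []
    for rec, p in zip(cohort.records, paths, strict=True):
        rows.append({
            "path": str(p), "subject_id": rec.subject_id, "label": rec.label,
            "age": rec.age, "weight": rec.weight, "height": rec.height,
            "sex": rec.sex,
        })
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return os.fspath(out_path)
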