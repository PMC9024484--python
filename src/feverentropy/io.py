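"""Cohort file I/O.

On-disk layout: one CSV per subject with header ``minute,temp_c``
(minute as a 0-based integer, temperature in degC, an *empty* field for
a missing sample), plus a cohort manifest CSV ``subject_id,file,label``
with ``file`` relative to the manifest's directory and label in
``{bacterial, other}``.  Minimal and diff-friendly; round-trips the
in-memory cohort exactly up to float formatting.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

from .preprocess import LABELS, TemperatureSeries

__all__ = ["CohortParseError", "read_cohort", "write_cohort"]

MANIFEST_NAME = "manifest.csv"


class CohortParseError(Exception):
    """Malformed cohort input, with the offending file and line."""

    def __init__(self, path, line: "int | None", message: str):
        self.path = str(path)
        self.line = line
        loc = f"{path}:{line}" if line is not None else str(path)
        super().__init__(f"{loc}: {message}")


def _read_series_file(path: Path) -> np.ndarray:
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["minute", "temp_c"]:
            raise CohortParseError(path, 1, "expected header 'minute,temp_c'")
        prev_minute = -1
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 2:
                raise CohortParseError(path, lineno, f"expected 2 fields, got {len(row)}")
            try:
                minute = int(row[0])
            except ValueError:
                raise CohortParseError(path, lineno, f"non-integer minute {row[0]!r}") from None
            if minute <= prev_minute:
                raise CohortParseError(
                    path, lineno, f"non-monotone minute {minute} after {prev_minute}"
                )
            if minute != prev_minute + 1:
                raise CohortParseError(
                    path, lineno, f"minute {minute} not consecutive after {prev_minute}"
                )
            prev_minute = minute
            cell = row[1].strip()
            if cell == "":
                values.append(math.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise CohortParseError(
                    path, lineno, f"non-numeric temperature {row[1]!r}"
                ) from None
    if not values:
        raise CohortParseError(path, None, "series file contains no samples")
    return np.asarray(values)


def read_cohort(manifest_path) -> "list[TemperatureSeries]":
    """Load a labelled cohort from a manifest CSV.

    Raises :class:`CohortParseError` (with file and line number) for an
    unknown label, duplicate subject, missing series file, non-monotone
    timestamps or a non-numeric temperature cell.
    """
    manifest_path = Path(manifest_path)
    cohort: list[TemperatureSeries] = []
    seen: set[str] = set()
    with open(manifest_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != ["subject_id", "file", "label"]:
            raise CohortParseError(manifest_path, 1, "expected header 'subject_id,file,label'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise CohortParseError(
                    manifest_path, lineno, f"expected 3 fields, got {len(row)}"
                )
            subject_id, rel_file, label = (cell.strip() for cell in row[:3])
            if label not in LABELS:
                raise CohortParseError(
                    manifest_path, lineno, f"unknown label {label!r}; expected one of {LABELS}"
                )
            if subject_id in seen:
                raise CohortParseError(
                    manifest_path, lineno, f"duplicate subject {subject_id!r}"
                )
            seen.add(subject_id)
            series_path = manifest_path.parent / rel_file
            if not series_path.exists():
                raise CohortParseError(
                    manifest_path, lineno, f"series file {rel_file!r} not found"
                )
            values = _read_series_file(series_path)
            cohort.append(TemperatureSeries(subject_id=subject_id, label=label, values=values))
    return cohort


def write_cohort(cohort: "list[TemperatureSeries]", outdir) -> Path:
    """Write per-subject series files and the manifest; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / MANIFEST_NAME
    with open(manifest_path, "w", newline="") as mfh:
        writer = csv.writer(mfh)
        writer.writerow(["subject_id", "file", "label"])
        for s in cohort:
            fname = f"{s.subject_id}.csv"
            writer.writerow([s.subject_id, fname, s.label])
            with open(outdir / fname, "w", newline="") as sfh:
                sw = csv.writer(sfh)
                sw.writerow(["minute", "temp_c"])
                for minute, value in enumerate(s.values):
                    sw.writerow([minute, "" if math.isnan(value) else repr(float(value))])
    return manifest_path
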