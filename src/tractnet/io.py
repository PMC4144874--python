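"""Plain-text file formats: matrices, motion logs, cohort manifests.

Everything is stored as delimited text so fixtures stay inspectable:
matrices as tab-delimited numbers with an optional header row of node
labels, motion logs as six-column whitespace text (FSL ``.par`` layout,
three translations then three rotations per volume), and the cohort
manifest as a CSV with one row per scan.

Floats are written with 17 significant digits, so a write/read round trip
is value-exact and repeated runs are byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, MotionLog, SubjectData, TractCountSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_motion_log",
    "write_motion_log",
    "write_cohort",
    "read_manifest",
    "ScanRecord",
]

_FLOAT_FMT = "%.17g"

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "onset_age",
    "scan_id",
    "counts_file",
    "voxels_file",
    "motion_file",
]


def write_matrix(path: str | Path, matrix: np.ndarray, labels: Sequence[str] | None = None) -> None:
    """Write a matrix as tab-delimited text, optionally preceded by a
    header row of node labels."""
    path = Path(path)
    matrix = np.asarray(matrix)
    with path.open("w", newline="\n") as fh:
        if labels is not None:
            if len(labels) != matrix.shape[1]:
                raise ValueError("one label per matrix column required")
            fh.write("\t".join(labels) + "\n")
        for row in matrix:
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Read a delimited text matrix; returns (matrix, labels-or-None).

    The first row is treated as a label header when its first field is not
    numeric. Both tab/whitespace and comma delimiters are accepted.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")

    def split(line: str) -> list[str]:
        return line.replace(",", "\t").split()

    first = split(lines[0])
    labels: tuple[str, ...] | None = None
    try:
        float(first[0])
    except ValueError:
        labels = tuple(first)
        lines = lines[1:]
    matrix = np.array([[float(v) for v in split(ln)] for ln in lines])
    if labels is not None and matrix.shape[1] != len(labels):
        raise ValueError(f"{path}: header has {len(labels)} labels for {matrix.shape[1]} columns")
    return matrix, labels


def write_motion_log(path: str | Path, log: MotionLog) -> None:
    with Path(path).open("w", newline="\n") as fh:
        for row in np.asarray(log.params, dtype=float):
            fh.write("  ".join(_FLOAT_FMT % v for v in row) + "\n")


def read_motion_log(path: str | Path, subject_id: str = "", scan_id: str = "") -> MotionLog:
    params = np.loadtxt(path, ndmin=2)
    return MotionLog(params, subject_id, scan_id)


@dataclass(frozen=True)
class ScanRecord:
    """One manifest row: a subject's scan with its file locations."""

    subject_id: str
    group: str
    onset_age: float | None
    scan_id: str
    counts_file: Path
    voxels_file: Path
    motion_file: Path

    def load(self, labels: Sequence[str] | None = None) -> tuple[TractCountSet, MotionLog]:
        counts, file_labels = read_matrix(self.counts_file)
        voxels = np.loadtxt(self.voxels_file).reshape(-1)
        use_labels = tuple(labels) if labels is not None else (file_labels or ())
        tc = TractCountSet(
            counts.astype(np.int64), voxels.astype(np.int64),
            self.subject_id, self.scan_id, use_labels,
        )
        return tc, read_motion_log(self.motion_file, self.subject_id, self.scan_id)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk (counts, voxels, motion logs, manifest.csv);
    returns the manifest path. File paths in the manifest are relative to
    the output directory."""
    out = Path(out_dir)
    for sub in ("counts", "voxels", "motion"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in cohort.subjects:
        voxels_rel = f"voxels/{subject.subject_id}.txt"
        first_tc = subject.scans[0][0]
        np.savetxt(out / voxels_rel, np.asarray(first_tc.voxels, dtype=int), fmt="%d")
        for tc, log in subject.scans:
            counts_rel = f"counts/{subject.subject_id}_{tc.scan_id}.txt"
            motion_rel = f"motion/{subject.subject_id}_{tc.scan_id}.par"
            write_matrix(out / counts_rel, np.asarray(tc.counts, dtype=float),
                         cohort.node_labels)
            write_motion_log(out / motion_rel, log)
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "onset_age": "" if subject.onset_age is None
                    else _FLOAT_FMT % subject.onset_age,
                    "scan_id": tc.scan_id,
                    "counts_file": counts_rel,
                    "voxels_file": voxels_rel,
                    "motion_file": motion_rel,
                }
            )
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="\n") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def read_manifest(manifest_path: str | Path) -> list[ScanRecord]:
    """Read a cohort manifest CSV; relative file paths are resolved against
    the manifest's directory."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    records = []
    for _, row in table.iterrows():
        onset = float(row["onset_age"]) if row["onset_age"] else None
        records.append(
            ScanRecord(
                subject_id=row["subject_id"],
                group=row["group"],
                onset_age=onset,
                scan_id=row["scan_id"],
                counts_file=base / row["counts_file"],
                voxels_file=base / row["voxels_file"],
                motion_file=base / row["motion_file"],
            )
        )
    return records
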