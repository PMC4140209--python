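"""RR-interval record handling: reading, artifact exclusion, cropping, cohorts.

The analysis operates on RR-interval (RRI) sequences — times in seconds
between consecutive heartbeats.  Preprocessing applies two rules before any
entropy is computed:

* intervals longer than 2.5 s are *deleted* (not interpolated) as recording
  artifacts, concatenating their neighbours; no low-side rule is applied;
* to make records comparable, every record is cropped to a common length
  ``N`` by removing samples from the beginning and the end in equal shares
  (on an odd remainder the extra sample comes off the end).

Cropping is applied after artifact filtering, which maximises the usable
length of each record.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    EmptyRecordError,
    InsufficientLengthError,
    InvalidInputError,
    RRIParseError,
)

__all__ = [
    "RRIRecord",
    "Cohort",
    "read_rri",
    "filter_artifacts",
    "crop_center",
    "prepare_cohorts",
    "load_manifest",
    "write_rejection_report",
    "MAX_RR_SECONDS",
]

#: Default artifact threshold: RR intervals strictly greater than this are excluded.
MAX_RR_SECONDS = 2.5


@dataclass(frozen=True)
class RRIRecord:
    """One subject's RR-interval sequence, in seconds."""

    id: str
    intervals: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidInputError(f"record {self.id!r}: intervals must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise InvalidInputError(f"record {self.id!r}: intervals must be positive and finite")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class Cohort:
    """A labelled group of RRI records (e.g. non-pathological vs pathological)."""

    label: str
    records: tuple[RRIRecord, ...]

    def __post_init__(self):
        if not self.label:
            raise InvalidInputError("cohort label must be non-empty")
        recs = tuple(self.records)
        if not recs:
            raise InvalidInputError(f"cohort {self.label!r} has no records")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)


def read_rri(path, id: str | None = None, source_label: str = "") -> RRIRecord:
    """Read an RRI record from a plain-text file.

    Accepts one interval (seconds) per line, or two-column CSV
    ``time,interval`` in which case the second column is used.  Blank lines
    are skipped.  A non-numeric token raises :class:`RRIParseError` carrying
    the 1-based line number.
    """
    path = Path(path)
    rec_id = id if id is not None else path.stem
    intervals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            token = s.split(",")[1].strip() if "," in s else s
            try:
                intervals.append(float(token))
            except ValueError:
                raise RRIParseError(
                    f"{path}: cannot parse {token!r} on line {lineno}", line=lineno
                ) from None
    if not intervals:
        raise EmptyRecordError(f"{path}: no intervals found")
    return RRIRecord(id=rec_id, intervals=np.asarray(intervals), source_label=source_label)


def filter_artifacts(record: RRIRecord, max_rr: float = MAX_RR_SECONDS) -> tuple[RRIRecord, int]:
    """Remove intervals strictly greater than ``max_rr`` seconds.

    Returns the filtered record and the number of intervals removed.  The
    boundary is strict: an interval of exactly ``max_rr`` is kept.  Raises
    :class:`EmptyRecordError` if nothing survives.
    """
    keep = record.intervals <= max_rr
    n_removed = int(np.count_nonzero(~keep))
    if n_removed == 0:
        return record, 0
    if not np.any(keep):
        raise EmptyRecordError(f"record {record.id!r}: all intervals exceed {max_rr} s")
    return replace(record, intervals=record.intervals[keep]), n_removed


def crop_center(record: RRIRecord, n: int) -> RRIRecord:
    """Crop a record to exactly ``n`` intervals, trimming both ends equally.

    ``floor((L - n) / 2)`` samples are dropped from the start and the
    remainder from the end, so an odd surplus removes one extra sample at the
    end.
    """
    if int(n) != n or n < 1:
        raise InvalidInputError(f"target length must be a positive integer, got {n!r}")
    n = int(n)
    length = len(record)
    if length < n:
        raise InsufficientLengthError(
            f"record {record.id!r} has {length} intervals, cannot crop to {n}"
        )
    if length == n:
        return record
    front = (length - n) // 2
    return replace(record, intervals=record.intervals[front : front + n])


def prepare_cohorts(
    cohorts: list[Cohort],
    n: int,
    max_rr: float = MAX_RR_SECONDS,
    strict: bool = False,
) -> tuple[list[Cohort], list[dict]]:
    """Apply artifact filtering then center-cropping to every record.

    Returns the prepared cohorts (all surviving records of length exactly
    ``n``) and a rejection report: one dict per dropped record with keys
    ``cohort``, ``record``, ``reason``.  With ``strict=True`` any rejection
    raises instead.  Idempotent on its own output.
    """
    if int(n) != n or n < 1:
        raise InvalidInputError(f"target length must be a positive integer, got {n!r}")
    labels = [c.label for c in cohorts]
    if len(set(labels)) != len(labels):
        raise InvalidInputError(f"cohort labels must be unique, got {labels}")
    prepared: list[Cohort] = []
    rejections: list[dict] = []
    for cohort in cohorts:
        kept: list[RRIRecord] = []
        for rec in cohort.records:
            try:
                filtered, _ = filter_artifacts(rec, max_rr=max_rr)
                kept.append(crop_center(filtered, n))
            except (EmptyRecordError, InsufficientLengthError) as exc:
                if strict:
                    raise
                rejections.append(
                    {"cohort": cohort.label, "record": rec.id, "reason": str(exc)}
                )
        if kept:
            prepared.append(Cohort(label=cohort.label, records=tuple(kept)))
        elif strict:
            raise EmptyRecordError(f"cohort {cohort.label!r}: no records survive preparation")
        else:
            rejections.append(
                {"cohort": cohort.label, "record": "*", "reason": "no records survive preparation"}
            )
    return prepared, rejections


def load_manifest(path) -> list[Cohort]:
    """Load cohorts from a YAML/JSON manifest mapping label -> list of file paths.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or not spec:
        raise InvalidInputError(f"{path}: manifest must map cohort labels to file lists")
    cohorts = []
    for label, files in spec.items():
        if not isinstance(files, list) or not files:
            raise InvalidInputError(f"{path}: cohort {label!r} must list at least one file")
        records = tuple(
            read_rri(path.parent / f if not Path(f).is_absolute() else f, source_label=str(label))
            for f in files
        )
        cohorts.append(Cohort(label=str(label), records=records))
    return cohorts


def write_rejection_report(rejections: list[dict], path) -> None:
    """Write the rejection report produced by :func:`prepare_cohorts` as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["cohort", "record", "reason"])
        writer.writeheader()
        writer.writerows(rejections)
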