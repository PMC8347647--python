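"""Timestamped block-room cohort records: parsing, validation and cleaning.

A raw cohort is a list of :class:`BlockRecord`, one per anesthetic, carrying
the four block-room timestamps (block-room entry, intrathecal injection,
block-room exit, OR entry).  Records with missing or internally inconsistent
timestamps are removed by :func:`apply_exclusions` under five rules:

R1  injection time absent
R2  injection strictly before block-room entry
R3  injection strictly after block-room exit
R4  injection strictly after OR entry
R5  block-room exit strictly after OR entry

Boundary equality never excludes: the rules use strict inequalities.  The
block-performance time of a clean record is the interval from block-room
entry to intrathecal injection, in fractional minutes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BlockRecord",
    "ExclusionReport",
    "DurationSample",
    "RULE_NAMES",
    "apply_exclusions",
    "compute_block_time",
    "read_cohort",
    "write_cohort",
    "read_durations",
    "write_durations",
]

BLOCK_TYPES = ("spinal", "cse")

#: Human-readable names of the five exclusion rules, in order R1..R5.
RULE_NAMES = (
    "missing_injection",
    "injection_before_entry",
    "injection_after_exit",
    "injection_after_or_entry",
    "exit_after_or_entry",
)

COHORT_COLUMNS = (
    "case_id",
    "block_type",
    "block_room_entry",
    "intrathecal_injection",
    "block_room_exit",
    "or_entry",
    "provider_category",
)

DURATION_COLUMNS = ("block_type", "duration_min")

#: Sanity bound: all timestamps of one record must fall within one day.
_MAX_SPAN = timedelta(days=1)


class RecordError(ValueError):
    """Raised for malformed records or files."""


@dataclass(frozen=True)
class BlockRecord:
    """One block-room case; timestamps may be internally inconsistent.

    ``intrathecal_injection`` is ``None`` when the injection time was never
    documented (exclusion rule R1).
    """

    case_id: str
    block_type: str
    block_room_entry: datetime
    intrathecal_injection: datetime | None
    block_room_exit: datetime
    or_entry: datetime
    provider_category: str = ""

    def __post_init__(self) -> None:
        if self.block_type not in BLOCK_TYPES:
            raise RecordError(
                f"record {self.case_id!r}: unknown block_type {self.block_type!r}"
            )
        stamps = [self.block_room_entry, self.block_room_exit, self.or_entry]
        if self.intrathecal_injection is not None:
            stamps.append(self.intrathecal_injection)
        if max(stamps) - min(stamps) > _MAX_SPAN:
            raise RecordError(
                f"record {self.case_id!r}: timestamps span more than one day"
            )

    def violated_rules(self) -> tuple[int, ...]:
        """Indices (1-based) of the exclusion rules this record triggers.

        Every rule is evaluated; there is no short-circuiting, so records
        violating several rules report all of them.
        """
        hits = []
        inj = self.intrathecal_injection
        if inj is None:
            hits.append(1)
        else:
            if inj < self.block_room_entry:
                hits.append(2)
            if inj > self.block_room_exit:
                hits.append(3)
            if inj > self.or_entry:
                hits.append(4)
        if self.block_room_exit > self.or_entry:
            hits.append(5)
        return tuple(hits)


@dataclass(frozen=True)
class ExclusionReport:
    """Per-rule and aggregate tallies from one pass of :func:`apply_exclusions`."""

    n_input: int
    n_missing_injection: int
    n_injection_before_entry: int
    n_injection_after_exit: int
    n_injection_after_or_entry: int
    n_exit_after_or_entry: int
    n_multi_criteria: int
    n_excluded_unique: int
    n_retained: int

    @property
    def rule_counts(self) -> tuple[int, int, int, int, int]:
        return (
            self.n_missing_injection,
            self.n_injection_before_entry,
            self.n_injection_after_exit,
            self.n_injection_after_or_entry,
            self.n_exit_after_or_entry,
        )

    def __post_init__(self) -> None:
        if self.n_retained != self.n_input - self.n_excluded_unique:
            raise ValueError("retained + excluded must partition the input")
        if self.n_excluded_unique > sum(self.rule_counts):
            raise ValueError("unique exclusions cannot exceed total rule flags")


@dataclass(frozen=True)
class DurationSample:
    """A labeled vector of block-performance times, in minutes."""

    block_type: str
    durations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.durations, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("durations must be a non-empty 1-d vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError("durations must be finite")
        if np.any(arr < 0):
            raise ValueError("durations must be non-negative")
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"unknown block_type {self.block_type!r}")
        arr.setflags(write=False)
        object.__setattr__(self, "durations", arr)

    @property
    def n(self) -> int:
        return int(self.durations.size)


def apply_exclusions(
    records: Sequence[BlockRecord],
) -> tuple[list[BlockRecord], ExclusionReport]:
    """Drop records violating any of the five consistency rules.

    Returns the retained records (input order preserved) and an
    :class:`ExclusionReport`.  A record is excluded iff it triggers at least
    one rule; per-rule counts tally every flag, so their sum can exceed the
    number of unique excluded records.
    """
    if not records:
        raise RecordError("cohort is empty")
    rule_counts = [0] * 5
    n_multi = 0
    retained: list[BlockRecord] = []
    n_excluded = 0
    for rec in records:
        hits = rec.violated_rules()
        if hits:
            n_excluded += 1
            if len(hits) > 1:
                n_multi += 1
            for r in hits:
                rule_counts[r - 1] += 1
        else:
            retained.append(rec)
    report = ExclusionReport(
        n_input=len(records),
        n_missing_injection=rule_counts[0],
        n_injection_before_entry=rule_counts[1],
        n_injection_after_exit=rule_counts[2],
        n_injection_after_or_entry=rule_counts[3],
        n_exit_after_or_entry=rule_counts[4],
        n_multi_criteria=n_multi,
        n_excluded_unique=n_excluded,
        n_retained=len(retained),
    )
    return retained, report


def compute_block_time(record: BlockRecord) -> float:
    """Block-performance time: entry to intrathecal injection, in minutes."""
    if record.violated_rules():
        raise RecordError(
            f"record {record.case_id!r} violates exclusion rules; clean the "
            "cohort with apply_exclusions first"
        )
    assert record.intrathecal_injection is not None
    delta = record.intrathecal_injection - record.block_room_entry
    return delta.total_seconds() / 60.0


def durations_from_records(
    records: Iterable[BlockRecord], block_type: str = "spinal"
) -> DurationSample:
    """Collect block times of clean records of one type into a sample."""
    vals = [
        compute_block_time(r) for r in records if r.block_type == block_type
    ]
    if not vals:
        raise RecordError(f"no records of block_type {block_type!r}")
    return DurationSample(block_type=block_type, durations=np.asarray(vals))


# ---------------------------------------------------------------------------
# CSV plumbing.  Timestamps are ISO 8601 in one local timezone; an empty cell
# means the timestamp is absent (only allowed for the injection time).
# ---------------------------------------------------------------------------

def _parse_stamp(text: str, case_id: str, column: str) -> datetime:
    try:
        return datetime.fromisoformat(text)
    except ValueError:
        raise RecordError(
            f"record {case_id!r}: unparseable timestamp {text!r} in column "
            f"{column!r}"
        ) from None


def read_cohort(path: str | Path) -> list[BlockRecord]:
    """Read a cohort CSV (columns per :data:`COHORT_COLUMNS`)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise RecordError(f"{path}: missing required column(s) {missing}")
        records = []
        for row in reader:
            cid = row["case_id"]
            inj_text = row["intrathecal_injection"]
            records.append(
                BlockRecord(
                    case_id=cid,
                    block_type=row["block_type"],
                    block_room_entry=_parse_stamp(
                        row["block_room_entry"], cid, "block_room_entry"
                    ),
                    intrathecal_injection=(
                        _parse_stamp(inj_text, cid, "intrathecal_injection")
                        if inj_text
                        else None
                    ),
                    block_room_exit=_parse_stamp(
                        row["block_room_exit"], cid, "block_room_exit"
                    ),
                    or_entry=_parse_stamp(row["or_entry"], cid, "or_entry"),
                    provider_category=row["provider_category"],
                )
            )
    if not records:
        raise RecordError(f"{path}: no records")
    return records


def write_cohort(records: Sequence[BlockRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.case_id,
                    r.block_type,
                    r.block_room_entry.isoformat(),
                    r.intrathecal_injection.isoformat()
                    if r.intrathecal_injection is not None
                    else "",
                    r.block_room_exit.isoformat(),
                    r.or_entry.isoformat(),
                    r.provider_category,
                ]
            )


def read_durations(path: str | Path) -> DurationSample:
    """Read a durations CSV (columns ``block_type,duration_min``).

    All rows must share one block type; negative or non-numeric durations
    are rejected.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in DURATION_COLUMNS if c not in header]
        if missing:
            raise RecordError(f"{path}: missing required column(s) {missing}")
        types: set[str] = set()
        vals: list[float] = []
        for row in reader:
            types.add(row["block_type"])
            try:
                vals.append(float(row["duration_min"]))
            except ValueError:
                raise RecordError(
                    f"{path}: non-numeric duration {row['duration_min']!r}"
                ) from None
    if not vals:
        raise RecordError(f"{path}: no durations")
    if len(types) != 1:
        raise RecordError(f"{path}: mixed block types {sorted(types)}")
    return DurationSample(block_type=types.pop(), durations=np.asarray(vals))


def write_durations(sample: DurationSample, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(DURATION_COLUMNS)
        for v in sample.durations:
            writer.writerow([sample.block_type, repr(float(v))])
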