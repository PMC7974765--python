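"""Domain types and I/O for flash-CGM trial data.

A flash continuous glucose monitor records an interstitial glucose estimate
every 15 minutes into an on-device buffer holding the most recent 8 hours of
samples.  Each scan of the device downloads that buffer; a continuous trace is
reconstructed by merging overlapping downloads.  Scans spaced further apart
than the buffer leave genuinely missing stretches, which are tracked as gap
intervals rather than interpolated.

Timestamps are stored timezone-aware (UTC instant plus the local offset in
which it was recorded); day-based metrics elsewhere in the package use the
local calendar day, since eating, scanning and annotation behaviours are
circadian.  Naive timestamps are accepted on input and interpreted as UTC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseSample",
    "GlucoseTrace",
    "ScanDownload",
    "AnnotationEvent",
    "StudyDesign",
    "StudyPeriod",
    "Arm",
    "SampleSource",
    "EventKind",
    "MergeResult",
    "ParseError",
    "IntegrityError",
    "InsufficientDataError",
    "parse_trace_table",
    "parse_events",
    "parse_design",
    "merge_scan_downloads",
    "slice_window",
]

#: Physiological plausibility bounds for a CGM reading, mg/dL (exclusive).
#: The device reporting range; values outside are rejected at parse.
GLUCOSE_MIN_MGDL = 0.0
GLUCOSE_MAX_MGDL = 500.0

#: Nominal sampling interval of the sensor.
DEFAULT_INTERVAL = timedelta(minutes=15)

#: On-device memory depth: samples older than this at scan time are lost.
DEFAULT_BUFFER = timedelta(hours=8)


class ParseError(ValueError):
    """Malformed input file (bad timestamp, column, enum value...)."""


class IntegrityError(ValueError):
    """Well-formed input that violates a domain invariant."""


class InsufficientDataError(ValueError):
    """A window does not contain enough samples for the requested analysis."""


class SampleSource(str, Enum):
    CGM_SCAN = "cgm_scan"
    FINGERSTICK = "fingerstick"


class EventKind(str, Enum):
    MEAL = "meal"
    EXERCISE = "exercise"
    ALCOHOL = "alcohol"
    MTT_START = "mtt_start"
    FINGERSTICK = "fingerstick"
    OTHER = "other"


class Arm(str, Enum):
    PRODUCT = "product"
    PLACEBO = "placebo"


def _as_aware(ts: datetime) -> datetime:
    """Interpret naive timestamps as UTC; pass aware ones through."""
    if ts.tzinfo is None:
        return ts.replace(tzinfo=timezone.utc)
    return ts


@dataclass(frozen=True)
class GlucoseSample:
    """One glucose reading: instant, concentration in mg/dL, and origin."""

    timestamp: datetime
    glucose: float
    source: SampleSource = SampleSource.CGM_SCAN

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _as_aware(self.timestamp))
        if not GLUCOSE_MIN_MGDL < self.glucose < GLUCOSE_MAX_MGDL:
            raise IntegrityError(
                f"glucose {self.glucose} mg/dL outside plausible range "
                f"({GLUCOSE_MIN_MGDL}, {GLUCOSE_MAX_MGDL}) at {self.timestamp}"
            )

    @property
    def local_day(self) -> date:
        """Calendar day in the offset the sample was recorded in."""
        return self.timestamp.date()


@dataclass(frozen=True)
class GlucoseTrace:
    """A subject's time-ordered glucose samples on a nominal 15-min grid.

    ``gaps`` lists intervals known to be unrecoverable (scan spacing exceeded
    the device buffer); analyses must not bridge them.
    """

    subject_id: str
    samples: tuple[GlucoseSample, ...]
    nominal_interval: timedelta = DEFAULT_INTERVAL
    gaps: tuple[tuple[datetime, datetime], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ts = [s.timestamp for s in self.samples]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise IntegrityError(
                    f"timestamps not strictly increasing: {a} then {b}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[GlucoseSample]:
        return iter(self.samples)

    @property
    def start(self) -> datetime:
        return self.samples[0].timestamp

    @property
    def end(self) -> datetime:
        return self.samples[-1].timestamp

    def times_epoch(self) -> np.ndarray:
        """Sample instants as seconds since the epoch (float64)."""
        return np.array([s.timestamp.timestamp() for s in self.samples])

    def values(self) -> np.ndarray:
        """Glucose values in mg/dL, aligned with :meth:`times_epoch`."""
        return np.array([s.glucose for s in self.samples], dtype=float)

    def local_days(self) -> list[date]:
        return [s.local_day for s in self.samples]

    def segments(self) -> list[tuple[int, int]]:
        """Contiguous index ranges [i, j) split at data gaps.

        A gap is either a reported unrecoverable interval or an inter-sample
        spacing beyond twice the nominal interval.
        """
        if not self.samples:
            return []
        limit = 2 * self.nominal_interval
        bounds = [0]
        for i in range(1, len(self.samples)):
            if self.samples[i].timestamp - self.samples[i - 1].timestamp > limit:
                bounds.append(i)
        bounds.append(len(self.samples))
        return [(a, b) for a, b in zip(bounds, bounds[1:])]


@dataclass(frozen=True)
class ScanDownload:
    """One device scan: the buffer contents at ``scan_time``."""

    scan_time: datetime
    samples: tuple[GlucoseSample, ...]
    buffer: timedelta = DEFAULT_BUFFER

    def __post_init__(self) -> None:
        object.__setattr__(self, "scan_time", _as_aware(self.scan_time))
        object.__setattr__(self, "samples", tuple(self.samples))
        lo = self.scan_time - self.buffer
        for s in self.samples:
            if not (lo < s.timestamp <= self.scan_time):
                raise IntegrityError(
                    f"sample at {s.timestamp} outside buffer window "
                    f"({lo}, {self.scan_time}]"
                )


@dataclass(frozen=True)
class AnnotationEvent:
    """A timestamped smartphone-app log entry."""

    subject_id: str
    timestamp: datetime
    kind: EventKind
    payload: str = ""
    value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamp", _as_aware(self.timestamp))
        if (self.value is not None) != (self.kind is EventKind.FINGERSTICK):
            raise IntegrityError(
                "a numeric value is present iff the event is a fingerstick "
                f"(kind={self.kind.value}, value={self.value})"
            )


@dataclass(frozen=True)
class StudyPeriod:
    arm: Arm
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", _as_aware(self.start))
        object.__setattr__(self, "end", _as_aware(self.end))
        if self.end <= self.start:
            raise IntegrityError("period end must follow period start")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass(frozen=True)
class StudyDesign:
    """Per-subject 2x2 cross-over layout: ordered arm periods and washouts."""

    subject_id: str
    periods: tuple[StudyPeriod, ...]
    washouts: tuple[tuple[datetime, datetime], ...] = ()
    period_bounds_days: tuple[float, float] = (13.0, 17.0)
    washout_bounds_days: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        object.__setattr__(
            self,
            "washouts",
            tuple((_as_aware(a), _as_aware(b)) for a, b in self.washouts),
        )
        for p, q in zip(self.periods, self.periods[1:]):
            if q.start < p.end:
                raise IntegrityError("periods overlap or are out of order")
        lo, hi = self.period_bounds_days
        for p in self.periods:
            d = p.duration / timedelta(days=1)
            if not lo <= d <= hi:
                raise IntegrityError(
                    f"period duration {d:.1f} d outside [{lo}, {hi}] d"
                )
        wlo, whi = self.washout_bounds_days
        for a, b in self.washouts:
            d = (b - a) / timedelta(days=1)
            if not wlo <= d <= whi:
                raise IntegrityError(
                    f"washout duration {d:.1f} d outside [{wlo}, {whi}] d"
                )

    def period_for_arm(self, arm: Arm) -> StudyPeriod:
        for p in self.periods:
            if p.arm is arm:
                return p
        raise KeyError(f"no {arm.value} period in design for {self.subject_id}")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ("subject_id", "timestamp", "glucose_mgdl", "source")
EVENT_COLUMNS = ("subject_id", "timestamp", "kind", "payload", "value")


def _parse_iso(text: str, row: int, path: str) -> datetime:
    try:
        return _as_aware(datetime.fromisoformat(str(text).strip()))
    except ValueError as exc:
        raise ParseError(f"{path} row {row}: bad ISO-8601 timestamp {text!r}") from exc


def parse_trace_table(path: str, subject_id: str) -> GlucoseTrace:
    """Read one subject's trace from the canonical CSV.

    Expected header: ``subject_id,timestamp,glucose_mgdl,source``.  Rows for
    other subjects are ignored; rows are sorted by time; duplicate timestamps
    with equal glucose collapse to one sample, conflicting values are an
    :class:`IntegrityError`.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    samples: dict[datetime, GlucoseSample] = {}
    for row in df.itertuples(index=True):
        if str(row.subject_id) != subject_id:
            continue
        ts = _parse_iso(row.timestamp, row.Index + 2, str(path))
        try:
            glucose = float(row.glucose_mgdl)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path} row {row.Index + 2}: bad glucose {row.glucose_mgdl!r}"
            ) from exc
        try:
            source = SampleSource(str(row.source).strip())
        except ValueError as exc:
            raise ParseError(
                f"{path} row {row.Index + 2}: unknown source {row.source!r}"
            ) from exc
        sample = GlucoseSample(ts, glucose, source)
        prev = samples.get(sample.timestamp)
        if prev is not None and prev.glucose != sample.glucose:
            raise IntegrityError(
                f"{path}: conflicting glucose at {ts} for {subject_id}: "
                f"{prev.glucose} vs {sample.glucose}"
            )
        samples[sample.timestamp] = sample
    ordered = tuple(samples[k] for k in sorted(samples))
    return GlucoseTrace(subject_id=subject_id, samples=ordered)


def write_trace_table(path: str, traces: Iterable[GlucoseTrace]) -> None:
    rows = [
        {
            "subject_id": t.subject_id,
            "timestamp": s.timestamp.isoformat(),
            "glucose_mgdl": round(s.glucose, 2),
            "source": s.source.value,
        }
        for t in traces
        for s in t.samples
    ]
    pd.DataFrame(rows, columns=list(TRACE_COLUMNS)).to_csv(path, index=False)


def _event_from_record(rec: dict, row: int, path: str) -> AnnotationEvent:
    ts = _parse_iso(rec["timestamp"], row, path)
    try:
        kind = EventKind(str(rec["kind"]).strip())
    except ValueError as exc:
        raise ParseError(f"{path} row {row}: unknown event kind {rec['kind']!r}") from exc
    raw = rec.get("value")
    value = None
    if raw is not None and str(raw).strip() not in ("", "nan"):
        value = float(raw)
    payload = rec.get("payload") or ""
    if isinstance(payload, float) and np.isnan(payload):
        payload = ""
    return AnnotationEvent(
        subject_id=str(rec["subject_id"]),
        timestamp=ts,
        kind=kind,
        payload=str(payload),
        value=value,
    )


def parse_events(path: str, subject_id: str | None = None) -> list[AnnotationEvent]:
    """Read annotation events from CSV or a JSON array (same keys).

    Events are returned in time order; ``subject_id=None`` keeps all subjects.
    """
    text_path = str(path)
    if text_path.endswith(".json"):
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise ParseError(f"{path}: expected a JSON array of event objects")
    else:
        df = pd.read_csv(path, dtype=str)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        records = df.to_dict(orient="records")
    events = [
        _event_from_record(rec, i + 2, text_path) for i, rec in enumerate(records)
    ]
    if subject_id is not None:
        events = [e for e in events if e.subject_id == subject_id]
    return sorted(events, key=lambda e: e.timestamp)


def write_events(path: str, events: Iterable[AnnotationEvent]) -> None:
    rows = [
        {
            "subject_id": e.subject_id,
            "timestamp": e.timestamp.isoformat(),
            "kind": e.kind.value,
            "payload": e.payload,
            "value": "" if e.value is None else e.value,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(path, index=False)


def parse_design(source: str | dict, **bounds) -> StudyDesign:
    """Build a :class:`StudyDesign` from a JSON file path or a parsed dict.

    Schema: ``{subject_id, periods: [{arm, start, end}], washouts: [{start, end}]}``
    with ISO-8601 instants.  ``bounds`` may override ``period_bounds_days`` /
    ``washout_bounds_days``.
    """
    if isinstance(source, (str,)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    periods = tuple(
        StudyPeriod(
            arm=Arm(p["arm"]),
            start=datetime.fromisoformat(p["start"]),
            end=datetime.fromisoformat(p["end"]),
        )
        for p in doc["periods"]
    )
    washouts = tuple(
        (datetime.fromisoformat(w["start"]), datetime.fromisoformat(w["end"]))
        for w in doc.get("washouts", [])
    )
    return StudyDesign(
        subject_id=str(doc["subject_id"]), periods=periods, washouts=washouts, **bounds
    )


def load_designs(path: str, **bounds) -> dict[str, StudyDesign]:
    """Read a design file holding one design object or an array of them."""
    with open(path) as fh:
        doc = json.load(fh)
    docs = doc if isinstance(doc, list) else [doc]
    designs = {d["subject_id"]: parse_design(d, **bounds) for d in docs}
    return designs


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "subject_id": design.subject_id,
        "periods": [
            {"arm": p.arm.value, "start": p.start.isoformat(), "end": p.end.isoformat()}
            for p in design.periods
        ],
        "washouts": [
            {"start": a.isoformat(), "end": b.isoformat()} for a, b in design.washouts
        ],
    }


# ---------------------------------------------------------------------------
# Trace reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergeResult:
    """Merged trace plus the unrecoverable gap intervals."""

    trace: GlucoseTrace
    gaps: tuple[tuple[datetime, datetime], ...]


def merge_scan_downloads(
    downloads: Sequence[ScanDownload],
    subject_id: str = "",
    nominal_interval: timedelta = DEFAULT_INTERVAL,
) -> MergeResult:
    """Union overlapping buffer downloads into one trace.

    Identical (timestamp, glucose) repeats — the normal consequence of scans
    closer together than the buffer depth — collapse silently; the same
    timestamp with different glucose is an :class:`IntegrityError`.  Whenever
    consecutive scans are further apart than the buffer, the stretch
    ``(previous scan, next scan - buffer]`` was never downloaded and is
    reported as a gap.
    """
    merged: dict[datetime, GlucoseSample] = {}
    for dl in downloads:
        for s in dl.samples:
            prev = merged.get(s.timestamp)
            if prev is not None and prev.glucose != s.glucose:
                raise IntegrityError(
                    f"conflicting glucose at {s.timestamp}: "
                    f"{prev.glucose} vs {s.glucose}"
                )
            merged[s.timestamp] = s
    gaps: list[tuple[datetime, datetime]] = []
    scan_times = sorted(dl.scan_time for dl in downloads)
    buffers = {dl.scan_time: dl.buffer for dl in downloads}
    for a, b in zip(scan_times, scan_times[1:]):
        buffer = buffers[b]
        if b - a > buffer:
            gaps.append((a, b - buffer))
    trace = GlucoseTrace(
        subject_id=subject_id,
        samples=tuple(merged[k] for k in sorted(merged)),
        nominal_interval=nominal_interval,
        gaps=tuple(gaps),
    )
    return MergeResult(trace=trace, gaps=tuple(gaps))


def slice_window(trace: GlucoseTrace, start: datetime, end: datetime) -> GlucoseTrace:
    """Samples with ``start <= timestamp <= end`` (closed interval).

    The closed convention makes the 2-h meal-tolerance window on the 15-min
    grid contain exactly nine samples.  An empty slice is allowed.
    """
    start, end = _as_aware(start), _as_aware(end)
    if start >= end:
        raise ValueError("slice start must precede end")
    kept = tuple(s for s in trace.samples if start <= s.timestamp <= end)
    gaps = tuple(
        (max(a, start), min(b, end)) for a, b in trace.gaps if a <= end and b >= start
    )
    return GlucoseTrace(
        subject_id=trace.subject_id,
        samples=kept,
        nominal_interval=trace.nominal_interval,
        gaps=gaps,
    )
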