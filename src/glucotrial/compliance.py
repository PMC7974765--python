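"""Compliance analytics from scan behaviour and app annotation logs.

A flash sensor only holds 8 hours of data, so letting more than 8 hours pass
between scans loses the stretch that aged out of memory: inter-scan intervals
measured against the buffer limit are a direct compliance readout.  Annotation
counts per day quantify engagement with the food-diary app, and a pre-MTT
fasting check verifies that the 6 hours before a self-administered meal test
were actually quiet.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from enum import Enum
from typing import Sequence

import numpy as np

from .core import AnnotationEvent, GlucoseTrace, _as_aware
from .peaks import PeakInterval

__all__ = [
    "ScanGapReport",
    "FastingCheck",
    "FastingVerdict",
    "AnnotationRateStats",
    "scan_gap_stats",
    "fasting_precheck",
    "annotation_rate_stats",
]


@dataclass(frozen=True)
class ScanGapReport:
    intervals_h: tuple[float, ...]
    n_over_limit: int
    data_lost_h: float  # total unsampled time: sum of max(0, interval - buffer)
    median_by_week: tuple[float, ...]  # NaN for weeks without intervals
    trend: int  # sign(last-week median - first-week median)


@dataclass(frozen=True)
class AnnotationRateStats:
    mean_per_day: float
    variance_mean_ratio: float
    per_day_counts: tuple[int, ...]
    weekly_trend: int  # sign(last-week mean - first-week mean)


class FastingVerdict(str, Enum):
    PASS = "pass"
    FLAGGED = "flagged"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass(frozen=True)
class FastingCheck:
    window_start: datetime
    window_end: datetime
    max_excursion: float  # range (max - min) of glucose over the window, mg/dL
    verdict: FastingVerdict


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def scan_gap_stats(
    scan_times: Sequence[datetime],
    buffer_hours: float = 8.0,
) -> ScanGapReport:
    """Inter-scan interval statistics against the device buffer.

    Data lost is the total time that aged out of the buffer:
    sum of max(0, interval - buffer) over consecutive scans.  Weekly medians
    are computed on 7-day blocks from the first scan; the trend is the sign of
    the change between the first and last week holding any interval.
    """
    if not scan_times:
        raise ValueError("need at least one scan")
    times = sorted(_as_aware(t) for t in scan_times)
    intervals = np.array(
        [(b - a) / timedelta(hours=1) for a, b in zip(times, times[1:])]
    )
    n_over = int(np.sum(intervals > buffer_hours))
    lost = float(np.sum(np.maximum(0.0, intervals - buffer_hours)))
    if intervals.size:
        week_idx = np.array(
            [int((a - times[0]) / timedelta(days=7)) for a in times[:-1]]
        )
        n_weeks = int(week_idx.max()) + 1
        medians = [
            float(np.median(intervals[week_idx == w]))
            if np.any(week_idx == w)
            else float("nan")
            for w in range(n_weeks)
        ]
        filled = [m for m in medians if not np.isnan(m)]
        trend = _sign(filled[-1] - filled[0]) if len(filled) >= 2 else 0
    else:
        medians, trend = [], 0
    return ScanGapReport(
        intervals_h=tuple(float(x) for x in intervals),
        n_over_limit=n_over,
        data_lost_h=lost,
        median_by_week=tuple(medians),
        trend=trend,
    )


def fasting_precheck(
    trace: GlucoseTrace,
    t0: datetime,
    fasting_hours: float = 6.0,
    excursion_limit: float = 25.0,
    peaks: Sequence[PeakInterval] = (),
) -> FastingCheck:
    """Was the pre-MTT window actually fasted?

    Over [t0 - fasting_hours, t0]: ``insufficient_data`` when fewer than 75%
    of the expected grid points are present; ``flagged`` when the glucose
    range exceeds ``excursion_limit`` mg/dL or any detected peak overlaps the
    window; ``pass`` otherwise.  The verdict depends only on glucose
    differences, so it is invariant to a constant shift of the trace.
    """
    t0 = _as_aware(t0)
    start = t0 - timedelta(hours=fasting_hours)
    in_window = [s for s in trace.samples if start <= s.timestamp <= t0]
    expected = int(round(fasting_hours * 60 / (trace.nominal_interval / timedelta(minutes=1)))) + 1
    if len(in_window) < 0.75 * expected:
        return FastingCheck(start, t0, float("nan"), FastingVerdict.INSUFFICIENT_DATA)
    vals = np.array([s.glucose for s in in_window])
    excursion = float(vals.max() - vals.min())
    overlapping = any(p.start <= t0 and p.end >= start for p in peaks)
    verdict = (
        FastingVerdict.FLAGGED
        if excursion > excursion_limit or overlapping
        else FastingVerdict.PASS
    )
    return FastingCheck(start, t0, excursion, verdict)


def annotation_rate_stats(
    events: Sequence[AnnotationEvent],
    span_days: int,
    start: datetime | None = None,
) -> AnnotationRateStats:
    """Logs-per-day statistics over a fixed span.

    Days without any log count as zero, so the mean is total logs / span.
    Dispersion is reported as the variance-to-mean ratio (sample variance,
    ddof=1).  The weekly trend compares mean daily counts of the first and
    last 7-day block.
    """
    if span_days < 1:
        raise ValueError("span must cover at least one day")
    if not events:
        counts = np.zeros(span_days, dtype=int)
    else:
        first_day = (start or min(e.timestamp for e in events)).date()
        counts = np.zeros(span_days, dtype=int)
        for e in events:
            offset = (e.timestamp.date() - first_day).days
            if 0 <= offset < span_days:
                counts[offset] += 1
    mean = float(counts.mean())
    var = float(counts.var(ddof=1)) if counts.size > 1 else 0.0
    ratio = var / mean if mean > 0 else 0.0
    weeks = [counts[i : i + 7] for i in range(0, span_days, 7)]
    trend = (
        _sign(float(weeks[-1].mean()) - float(weeks[0].mean()))
        if len(weeks) >= 2
        else 0
    )
    return AnnotationRateStats(
        mean_per_day=mean,
        variance_mean_ratio=ratio,
        per_day_counts=tuple(int(c) for c in counts),
        weekly_trend=trend,
    )
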