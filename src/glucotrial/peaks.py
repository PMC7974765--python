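"""Spike-function peak detection for glucose traces.

Scoring follows Palshikar's S1 spike function: each point is scored by the
mean of its maximum rise over the k samples to the left and the k samples to
the right.  Points scoring above mean + h*sd of the positive scores are
clustered into candidate apexes, each apex's extent is walked outward to where
glucose returns near the local baseline, and candidates below a prominence
floor are dropped — separating meal-induced excursions from sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import AnnotationEvent, EventKind, GlucoseTrace

__all__ = [
    "PeakParams",
    "PeakInterval",
    "PeakSummary",
    "MatchResult",
    "spike_score",
    "detect_peaks",
    "peak_summaries",
    "match_peaks_to_events",
]


@dataclass(frozen=True)
class PeakParams:
    """Detection knobs.

    k is the scoring neighbourhood in samples (4 = one hour each side on the
    15-min grid); h the threshold in SDs of the positive scores; candidates
    closer than merge_window collapse; prominences below min_prominence
    (mg/dL above the local baseline) are discarded; smoothing is the moving-
    average width applied before scoring.
    """

    k: int = 4
    h: float = 1.0
    merge_window_min: float = 60.0
    min_prominence: float = 20.0
    smoothing: int = 3
    rise_tolerance: float = 5.0  # mg/dL rise above the running minimum that
    # terminates the extent walk (noise guard on the monotone-flank criterion)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.merge_window_min < 0:
            raise ValueError("merge_window must be non-negative")


@dataclass(frozen=True)
class PeakInterval:
    """A detected glucose excursion."""

    start: datetime
    apex: datetime
    end: datetime
    apex_glucose: float
    local_baseline: float
    prominence: float
    score: float

    def __post_init__(self) -> None:
        if not self.start <= self.apex <= self.end:
            raise ValueError("peak must satisfy start <= apex <= end")

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


def spike_score(series: Sequence[float], k: int = 4) -> np.ndarray:
    """Palshikar S1 spike scores.

    score(i) = 0.5 * [max_{j=1..k}(x_i - x_{i-j}) + max_{j=1..k}(x_i - x_{i+j})];
    at the boundaries only the available one-sided neighbourhood contributes
    (the first and last points use a single-sided score).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n <= 2 * k:
        raise ValueError(f"series of length {n} too short for k={k} (need > {2 * k})")
    scores = np.empty(n)
    for i in range(n):
        left = x[i] - x[max(0, i - k) : i]
        right = x[i] - x[i + 1 : i + 1 + k]
        sides = [s.max() for s in (left, right) if s.size]
        scores[i] = float(np.mean(sides))
    return scores


def _clusters(indices: np.ndarray, times_s: np.ndarray, window_s: float) -> list[list[int]]:
    """Group kept indices whose successive times are closer than the window."""
    groups: list[list[int]] = []
    for idx in indices:
        if groups and times_s[idx] - times_s[groups[-1][-1]] < window_s:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    return groups


def _walk_extent(
    smoothed: np.ndarray, apex: int, lo: int, hi: int, tol: float
) -> tuple[int, int]:
    """Indices of the flank minima around the apex, within [lo, hi).

    Walks outward tracking the running minimum; the walk ends where the curve
    rises more than ``tol`` above it (a genuine valley) or at the segment
    edge, so sample-to-sample noise does not truncate the descent.
    """

    def _one_side(step: int, limit: int) -> int:
        j = apex
        min_idx, min_val = apex, smoothed[apex]
        while j != limit:
            nxt = smoothed[j + step]
            if nxt < min_val:
                min_val, min_idx = nxt, j + step
            elif nxt > min_val + tol:
                break
            j += step
        return min_idx

    return _one_side(-1, lo), _one_side(+1, hi - 1)


def detect_peaks(trace: GlucoseTrace, params: PeakParams = PeakParams()) -> list[PeakInterval]:
    """Detect glucose peaks; returned in time order, pairwise disjoint.

    Pipeline: moving-average smoothing, S1 scoring, thresholding at
    mean + h*sd of the positive scores, clustering within merge_window (apex =
    maximum raw glucose of the cluster), extent walking (outward along the
    flanks, trimmed to where glucose returns within 10% of the prominence
    above the local baseline), and a prominence floor.  The trace is processed
    per contiguous segment, so peaks never span a data gap.
    """
    values = trace.values()
    times_s = trace.times_epoch()
    peaks: list[PeakInterval] = []
    window_s = params.merge_window_min * 60.0

    for lo, hi in trace.segments():
        seg = values[lo:hi]
        if seg.size <= 2 * params.k:
            continue
        smoothed = (
            uniform_filter1d(seg, size=params.smoothing, mode="nearest")
            if params.smoothing > 1
            else seg
        )
        scores = spike_score(smoothed, params.k)
        pos = scores[scores > 0]
        if pos.size == 0:
            continue
        threshold = pos.mean() + params.h * pos.std()
        kept = np.nonzero(scores > threshold)[0]
        if kept.size == 0:
            continue
        for cluster in _clusters(kept, times_s[lo:hi], window_s):
            # high scores sit on the steep rise; hill-climb the smoothed curve
            # from the cluster to the actual local maximum
            apex = cluster[int(np.argmax(smoothed[cluster]))]
            while apex + 1 < seg.size and smoothed[apex + 1] > smoothed[apex]:
                apex += 1
            while apex > 0 and smoothed[apex - 1] > smoothed[apex]:
                apex -= 1
            left, right = _walk_extent(smoothed, apex, 0, seg.size, params.rise_tolerance)
            # report the raw sample nearest the smoothed apex as the apex
            window = range(max(left, apex - params.smoothing), min(right, apex + params.smoothing) + 1)
            raw_apex = max(window, key=lambda i: seg[i])
            local_baseline = float(max(smoothed[left], smoothed[right]))
            prominence = float(seg[raw_apex] - local_baseline)
            if prominence < params.min_prominence:
                continue
            # trim flanks to the 10%-of-prominence return level
            level = local_baseline + 0.1 * prominence
            start = apex
            while start > left and smoothed[start - 1] > level:
                start -= 1
            end = apex
            while end < right and smoothed[end + 1] > level:
                end += 1
            start, end = min(start, raw_apex), max(end, raw_apex)
            apex = raw_apex
            peaks.append(
                PeakInterval(
                    start=trace.samples[lo + start].timestamp,
                    apex=trace.samples[lo + apex].timestamp,
                    end=trace.samples[lo + end].timestamp,
                    apex_glucose=float(seg[apex]),
                    local_baseline=local_baseline,
                    prominence=prominence,
                    score=float(scores[apex]),
                )
            )

    # enforce disjointness: clip any overlap at the earlier peak's end
    peaks.sort(key=lambda p: p.start)
    out: list[PeakInterval] = []
    for p in peaks:
        if out and p.start < out[-1].end:
            if p.apex <= out[-1].end:
                continue  # fully shadowed by the previous extent
            p = PeakInterval(
                start=out[-1].end,
                apex=p.apex,
                end=p.end,
                apex_glucose=p.apex_glucose,
                local_baseline=p.local_baseline,
                prominence=p.prominence,
                score=p.score,
            )
        out.append(p)
    return out


@dataclass(frozen=True)
class PeakSummary:
    """Per-local-day peak statistics and their means."""

    days: tuple[date, ...]
    peaks_per_day: tuple[int, ...]
    in_peak_minutes: tuple[float, ...]
    in_peak_fraction: tuple[float, ...]  # of sampled time that day
    mean_peaks_per_day: float
    mean_in_peak_minutes: float
    mean_in_peak_fraction: float


def peak_summaries(trace: GlucoseTrace, peaks: Sequence[PeakInterval]) -> PeakSummary:
    """Daily peak counts and time-in-peak on local calendar days.

    A peak counts on the day of its apex; its duration is clipped at local
    midnight when it straddles days.  The in-peak fraction divides by the
    sampled time of the day (samples x nominal interval), so partially
    monitored days are not diluted by unworn hours.
    """
    day_list = sorted(set(trace.local_days()))
    counts = {d: 0 for d in day_list}
    minutes = {d: 0.0 for d in day_list}
    sampled = {d: 0.0 for d in day_list}
    step_min = trace.nominal_interval / timedelta(minutes=1)
    for s in trace.samples:
        sampled[s.local_day] += step_min
    for p in peaks:
        if p.apex.date() in counts:
            counts[p.apex.date()] += 1
        t = p.start
        while t < p.end:
            day_end = datetime.combine(
                t.date() + timedelta(days=1), datetime.min.time(), tzinfo=t.tzinfo
            )
            chunk_end = min(p.end, day_end)
            if t.date() in minutes:
                minutes[t.date()] += (chunk_end - t) / timedelta(minutes=1)
            t = chunk_end
    fractions = tuple(
        minutes[d] / sampled[d] if sampled[d] > 0 else 0.0 for d in day_list
    )
    n_days = max(len(day_list), 1)
    return PeakSummary(
        days=tuple(day_list),
        peaks_per_day=tuple(counts[d] for d in day_list),
        in_peak_minutes=tuple(minutes[d] for d in day_list),
        in_peak_fraction=fractions,
        mean_peaks_per_day=sum(counts.values()) / n_days,
        mean_in_peak_minutes=sum(minutes.values()) / n_days,
        mean_in_peak_fraction=sum(fractions) / n_days if day_list else 0.0,
    )


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[tuple[AnnotationEvent, PeakInterval, float], ...]  # lag in min
    unmatched_events: tuple[AnnotationEvent, ...]
    unmatched_peaks: tuple[PeakInterval, ...]


def match_peaks_to_events(
    peaks: Sequence[PeakInterval],
    events: Sequence[AnnotationEvent],
    max_lag_min: float = 90.0,
) -> MatchResult:
    """Greedy chronological matching of meal annotations to peak starts.

    Each meal event (in time order) claims the first unclaimed peak whose
    start lies in [event - 15 min, event + max_lag]; the small negative
    allowance absorbs annotation lag after eating began.  Lags are reported in
    minutes (peak start minus event time).
    """
    meal_events = sorted(
        (e for e in events if e.kind is EventKind.MEAL), key=lambda e: e.timestamp
    )
    ordered_peaks = sorted(peaks, key=lambda p: p.start)
    taken = [False] * len(ordered_peaks)
    matches = []
    unmatched_events = []
    for ev in meal_events:
        lo = ev.timestamp - timedelta(minutes=15)
        hi = ev.timestamp + timedelta(minutes=max_lag_min)
        for i, p in enumerate(ordered_peaks):
            if taken[i] or not lo <= p.start <= hi:
                continue
            taken[i] = True
            lag = (p.start - ev.timestamp) / timedelta(minutes=1)
            matches.append((ev, p, lag))
            break
        else:
            unmatched_events.append(ev)
    unmatched_peaks = tuple(p for i, p in enumerate(ordered_peaks) if not taken[i])
    return MatchResult(
        matches=tuple(matches),
        unmatched_events=tuple(unmatched_events),
        unmatched_peaks=unmatched_peaks,
    )
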