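"""Consensus per-subject glycemic metrics.

Time in range (70-180 mg/dL, boundaries inclusive), hypoglycemic episodes
(strictly below 70 mg/dL for at least two consecutive 15-min samples, i.e.
at least 30 minutes, never bridged across data gaps), the 2-h postprandial
intolerance flag (>= 140 mg/dL two hours after a meal), and a subject-level
summary whose band percentages partition the sampled time exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .core import GlucoseTrace, InsufficientDataError, _as_aware

__all__ = [
    "MetricThresholds",
    "HypoEpisode",
    "PostprandialCheck",
    "SubjectSummary",
    "time_in_range",
    "hypoglycemic_episodes",
    "postprandial_intolerance_flag",
    "subject_summary",
]


@dataclass(frozen=True)
class MetricThresholds:
    """Consensus thresholds, mg/dL unless noted."""

    hypo_mgdl: float = 70.0
    range_low_mgdl: float = 70.0
    range_high_mgdl: float = 180.0
    postprandial_mgdl: float = 140.0
    hypo_min_consecutive: int = 2  # samples (30 min on the 15-min grid)

    def __post_init__(self) -> None:
        if self.range_low_mgdl >= self.range_high_mgdl:
            raise ValueError("range_low must be below range_high")
        if min(self.hypo_mgdl, self.range_low_mgdl, self.postprandial_mgdl) <= 0:
            raise ValueError("thresholds must be positive")


DEFAULT_THRESHOLDS = MetricThresholds()


@dataclass(frozen=True)
class HypoEpisode:
    start: datetime
    end: datetime
    nadir: float
    n_samples: int


@dataclass(frozen=True)
class PostprandialCheck:
    intolerant: bool
    glucose: float  # value used at meal + 120 min
    interpolated: bool


@dataclass(frozen=True)
class SubjectSummary:
    mean_glucose: float
    sd_glucose: float
    cv: float  # coefficient of variation, SD/mean
    pct_below_range: float
    pct_in_range: float
    pct_above_range: float
    n_hypo_episodes: int
    n_samples: int


def time_in_range(
    trace: GlucoseTrace,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Fraction of sampled time with range_low <= glucose <= range_high.

    Each sample stands for its nominal interval, so this is simply the sample
    fraction; both boundaries are inclusive.
    """
    if not trace.samples:
        raise ValueError("empty trace")
    v = trace.values()
    return float(
        np.mean((v >= thresholds.range_low_mgdl) & (v <= thresholds.range_high_mgdl))
    )


def hypoglycemic_episodes(
    trace: GlucoseTrace,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> list[HypoEpisode]:
    """Maximal runs of consecutive samples strictly below the hypo threshold.

    Runs shorter than ``hypo_min_consecutive`` samples are discarded, and runs
    separated by a data gap are never joined (consecutive-sample semantics
    require contiguity).
    """
    episodes: list[HypoEpisode] = []
    for lo, hi in trace.segments():
        run_start = None
        for i in range(lo, hi + 1):
            below = i < hi and trace.samples[i].glucose < thresholds.hypo_mgdl
            if below and run_start is None:
                run_start = i
            elif not below and run_start is not None:
                n = i - run_start
                if n >= thresholds.hypo_min_consecutive:
                    run = trace.samples[run_start:i]
                    episodes.append(
                        HypoEpisode(
                            start=run[0].timestamp,
                            end=run[-1].timestamp,
                            nadir=min(s.glucose for s in run),
                            n_samples=n,
                        )
                    )
                run_start = None
    return episodes


def postprandial_intolerance_flag(
    trace: GlucoseTrace,
    meal_time: datetime,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> PostprandialCheck:
    """Glucose-intolerance flag from the 2-h postprandial value.

    The value at meal + 120 min is the nearest sample within 15 min, else the
    linear interpolation between the bracketing samples; the flag is true when
    it reaches ``postprandial_mgdl`` (>= comparison).
    """
    target = _as_aware(meal_time) + timedelta(minutes=120)
    if not trace.samples:
        raise InsufficientDataError("empty trace")
    times = trace.times_epoch()
    vals = trace.values()
    g = target.timestamp()
    j = int(np.argmin(np.abs(times - g)))
    if abs(times[j] - g) <= 15 * 60:
        value, interpolated = float(vals[j]), False
    else:
        right = int(np.searchsorted(times, g))
        if right == 0 or right == times.size:
            raise InsufficientDataError(
                f"no sample within 15 min of {target} and no bracketing pair"
            )
        left = right - 1
        frac = (g - times[left]) / (times[right] - times[left])
        value = float(vals[left] + frac * (vals[right] - vals[left]))
        interpolated = True
    return PostprandialCheck(
        intolerant=value >= thresholds.postprandial_mgdl,
        glucose=value,
        interpolated=interpolated,
    )


def subject_summary(
    trace: GlucoseTrace,
    thresholds: MetricThresholds = DEFAULT_THRESHOLDS,
) -> SubjectSummary:
    """Subject-level glycemic summary.

    The three band percentages (< low, in range, > high) are computed from
    sample counts and partition 100% of the sampled time exactly.  SD is the
    sample standard deviation (ddof=1, zero for a single sample).
    """
    if not trace.samples:
        raise ValueError("empty trace")
    v = trace.values()
    n = v.size
    below = int(np.sum(v < thresholds.range_low_mgdl))
    above = int(np.sum(v > thresholds.range_high_mgdl))
    within = n - below - above
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    return SubjectSummary(
        mean_glucose=mean,
        sd_glucose=sd,
        cv=sd / mean,
        pct_below_range=100.0 * below / n,
        pct_in_range=100.0 * within / n,
        pct_above_range=100.0 * above / n,
        n_hypo_episodes=len(hypoglycemic_episodes(trace, thresholds)),
        n_samples=n,
    )
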