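"""Seeded synthetic CGM data with the statistical structure the pipeline assumes.

The generator emulates a flash-CGM cross-over study: interstitial glucose on a
15-minute grid (subject baseline + a dawn-phase circadian sinusoid + unimodal
meal excursions + sensor noise), self-administered meal-tolerance tests (MTTs)
with a tunable treatment effect, scan behaviour with study fatigue against an
8-hour device buffer, app annotation logs, and 2x2 cross-over layouts with
13-17-day periods separated by 3-6-day washouts.

It is deliberately phenomenological: the meal impulse is a gamma-density-shaped
curve pinned to a stated apex, not an insulin-glucose ODE model, and no attempt
is made to fit any real subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .core import (
    AnnotationEvent,
    Arm,
    EventKind,
    GlucoseSample,
    GlucoseTrace,
    SampleSource,
    ScanDownload,
    StudyDesign,
    StudyPeriod,
)

__all__ = [
    "TraceGenParams",
    "MealResponseParams",
    "CrossoverEffectParams",
    "ScanBehaviorParams",
    "StudyBundle",
    "simulate_trace",
    "simulate_mtt_response",
    "simulate_crossover_cohort",
    "simulate_scan_records",
    "downloads_from_scan_times",
    "simulate_study",
]

#: Default study timezone (US Pacific standard offset); circadian terms and
#: day-based metrics are computed on this local clock.
STUDY_TZ = timezone(timedelta(hours=-8))

DEFAULT_START = datetime(2018, 3, 1, 0, 0, tzinfo=STUDY_TZ)

#: Values are clipped to this floor (mg/dL) so additive noise cannot produce
#: nonphysical readings while keeping hypoglycemia testable.
CLIP_FLOOR = 40.0
CLIP_CEIL = 495.0


@dataclass(frozen=True)
class TraceGenParams:
    """Background-trace parameters (all glucose quantities in mg/dL)."""

    baseline_mean: float = 95.0
    baseline_sd_between_subject: float = 10.0
    circadian_amplitude: float = 8.0
    noise_sd: float = 5.0
    noise_autocorr: float = 0.0  # optional AR(1) coefficient of sensor noise
    sampling_interval_min: float = 15.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.baseline_sd_between_subject, self.noise_sd) < 0:
            raise ValueError("dispersions must be non-negative")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")
        if not 0 <= self.noise_autocorr < 1:
            raise ValueError("noise_autocorr must lie in [0, 1)")


@dataclass(frozen=True)
class MealResponseParams:
    """Gamma-density-shaped postprandial excursion.

    The apex equals ``carbs_g * peak_height_per_g`` mg/dL above the ambient
    level, reached ``time_to_peak`` minutes after the meal; by ``return_time``
    the excursion has decayed to 5% of the apex.  The standard MTT drink is
    45 g of carbohydrates.
    """

    carbs_g: float = 45.0
    peak_height_per_g: float = 1.2
    time_to_peak_min: float = 45.0
    return_time_min: float = 120.0

    def __post_init__(self) -> None:
        if self.time_to_peak_min >= self.return_time_min:
            raise ValueError("time_to_peak must precede return_time")
        if self.carbs_g < 0 or self.peak_height_per_g < 0:
            raise ValueError("meal height must be non-negative")

    @property
    def apex_height(self) -> float:
        return self.carbs_g * self.peak_height_per_g

    def impulse(self, minutes_since_meal: np.ndarray) -> np.ndarray:
        """Excursion (mg/dL) at each time offset; zero before the meal."""
        t = np.asarray(minutes_since_meal, dtype=float)
        tp = self.time_to_peak_min
        r = self.return_time_min / tp
        # shape exponent pinning the decay to 5% of apex at return_time
        a = np.log(20.0) / ((r - 1.0) - np.log(r))
        out = np.zeros_like(t)
        pos = t > 0
        x = t[pos] / tp
        out[pos] = self.apex_height * np.exp(a * (np.log(x) + 1.0 - x))
        return out


@dataclass(frozen=True)
class CrossoverEffectParams:
    """Population law of the per-subject treatment contrast ddAUC, (mg/dL)*min."""

    delta_delta_mean: float
    delta_delta_sd: float
    n_subjects: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.delta_delta_sd <= 0:
            raise ValueError("delta_delta_sd must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass(frozen=True)
class ScanBehaviorParams:
    """Inter-scan interval model with study fatigue.

    Intervals are log-normal around a weekly drifting median; with probability
    ``overshoot_prob`` an interval instead exceeds the device buffer, losing
    the stretch that aged out of memory.
    """

    median_interval_h: float = 5.0
    fatigue_drift: float = 1.1  # multiplicative increase of the median per week
    overshoot_prob: float = 0.05
    interval_log_sd: float = 0.3
    buffer_h: float = 8.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.overshoot_prob <= 1:
            raise ValueError("overshoot_prob must be a probability")
        if self.median_interval_h <= 0 or self.buffer_h <= 0:
            raise ValueError("intervals must be positive")


def simulate_trace(
    params: TraceGenParams,
    duration_days: float,
    meals: tuple[tuple[datetime, MealResponseParams], ...] = (),
    subject_id: str = "S1",
    start: datetime = DEFAULT_START,
    rng: np.random.Generator | None = None,
) -> GlucoseTrace:
    """One subject's trace: baseline + circadian + meal impulses + noise.

    One sample per ``sampling_interval_min`` over ``[start, start + duration)``
    (half-open: one day at 15 min gives 96 samples).  Reproducible for a fixed
    seed.  Values falling below 40 mg/dL are clipped with a warning.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    step = timedelta(minutes=params.sampling_interval_min)
    n = int(round(duration_days * 24 * 60 / params.sampling_interval_min))
    times = [start + i * step for i in range(n)]

    baseline = params.baseline_mean + rng.normal(0.0, params.baseline_sd_between_subject)
    hours = np.array([t.hour + t.minute / 60.0 for t in times])
    # dawn-phase rise: circadian term peaks at 08:00 local
    circ = params.circadian_amplitude * np.cos(2 * np.pi * (hours - 8.0) / 24.0)

    t_epoch = np.array([t.timestamp() for t in times])
    meal_term = np.zeros(n)
    for meal_time, mp in meals:
        meal_term += mp.impulse((t_epoch - meal_time.timestamp()) / 60.0)

    eps = rng.normal(0.0, params.noise_sd, size=n)
    if params.noise_autocorr > 0:
        rho = params.noise_autocorr
        ar = np.empty(n)
        ar[0] = eps[0]
        for i in range(1, n):
            ar[i] = rho * ar[i - 1] + np.sqrt(1 - rho**2) * eps[i]
        eps = ar

    vals = baseline + circ + meal_term + eps
    n_clipped = int(np.sum(vals < CLIP_FLOOR) + np.sum(vals > CLIP_CEIL))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} simulated samples clipped to [{CLIP_FLOOR}, {CLIP_CEIL}] mg/dL",
            stacklevel=2,
        )
    vals = np.clip(vals, CLIP_FLOOR, CLIP_CEIL)
    samples = tuple(
        GlucoseSample(ts, float(v), SampleSource.CGM_SCAN) for ts, v in zip(times, vals)
    )
    return GlucoseTrace(subject_id=subject_id, samples=samples, nominal_interval=step)


def simulate_mtt_response(
    params: MealResponseParams,
    effect_multiplier: float,
    baseline: float,
    t0: datetime = DEFAULT_START,
    subject_id: str = "S1",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GlucoseTrace:
    """A 2-h MTT segment: nine samples on the closed [0, 120]-min grid.

    The incremental response above ``baseline`` is the meal impulse scaled by
    ``effect_multiplier``, so the incremental AUC is exactly linear in the
    multiplier when ``noise_sd`` is zero.
    """
    if effect_multiplier < 0:
        raise ValueError("effect_multiplier must be non-negative")
    offsets = np.arange(9) * 15.0
    vals = baseline + effect_multiplier * params.impulse(offsets)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        vals = vals + rng.normal(0.0, noise_sd, size=vals.size)
    samples = tuple(
        GlucoseSample(t0 + timedelta(minutes=float(m)), float(v))
        for m, v in zip(offsets, vals)
    )
    return GlucoseTrace(subject_id=subject_id, samples=samples)


def simulate_crossover_cohort(params: CrossoverEffectParams) -> pd.DataFrame:
    """Per-subject ddAUC table drawn from the stated normal law.

    Columns: ``subject``, ``delta_auc_placebo``, ``delta_auc_product``,
    ``delta_delta_auc`` with ``delta_delta_auc = product - placebo`` exactly.
    The placebo-arm component gets its own between-subject spread so the two
    arm columns are individually plausible.
    """
    rng = np.random.default_rng(params.seed)
    dd = rng.normal(params.delta_delta_mean, params.delta_delta_sd, params.n_subjects)
    placebo = rng.normal(500.0, 600.0, params.n_subjects)
    return pd.DataFrame(
        {
            "subject": [f"S{i + 1}" for i in range(params.n_subjects)],
            "delta_auc_placebo": placebo,
            "delta_auc_product": placebo + dd,
            "delta_delta_auc": dd,
        }
    )


def downloads_from_scan_times(
    trace: GlucoseTrace,
    scan_times: list[datetime],
    buffer_h: float = 8.0,
) -> list[ScanDownload]:
    """Buffer contents at each scan: samples in ``(scan - buffer, scan]``."""
    buffer = timedelta(hours=buffer_h)
    out = []
    for st in scan_times:
        window = tuple(
            s for s in trace.samples if st - buffer < s.timestamp <= st
        )
        out.append(ScanDownload(scan_time=st, samples=window, buffer=buffer))
    return out


def simulate_scan_times(
    params: ScanBehaviorParams,
    start: datetime,
    end: datetime,
    rng: np.random.Generator | None = None,
) -> list[datetime]:
    """Scan instants over (start, end]: drifting log-normal intervals."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    times: list[datetime] = []
    t = start
    while t < end:
        week = int((t - start) / timedelta(days=7))
        median_h = params.median_interval_h * params.fatigue_drift**week
        if rng.uniform() < params.overshoot_prob:
            gap_h = params.buffer_h + rng.uniform(0.25, 3.0)
        else:
            gap_h = median_h * np.exp(rng.normal(0.0, params.interval_log_sd))
            gap_h = min(gap_h, params.buffer_h)  # compliant scans respect the buffer
        t = t + timedelta(hours=float(gap_h))
        times.append(t)
    return times


def simulate_scan_records(
    params: ScanBehaviorParams,
    trace: GlucoseTrace,
    rng: np.random.Generator | None = None,
) -> list[ScanDownload]:
    """Scan the trace with drifting intervals; overshoots lose aged-out data."""
    if not trace.samples:
        raise ValueError("trace must be non-empty")
    scan_times = simulate_scan_times(params, trace.start, trace.end, rng=rng)
    return downloads_from_scan_times(trace, scan_times, buffer_h=params.buffer_h)


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyBundle:
    """A complete synthetic cross-over study in the pipeline's input formats."""

    traces: dict[str, GlucoseTrace]
    events: list[AnnotationEvent]
    designs: dict[str, StudyDesign]
    scan_times: dict[str, list[datetime]]
    truth: dict


def _meal_schedule(
    days: list[date],
    mtt_days: set[date],
    rng: np.random.Generator,
    tz: timezone,
) -> list[tuple[datetime, MealResponseParams]]:
    """Three daily meals with jitter; breakfast skipped on MTT days (fasting)."""
    meals = []
    for d in days:
        for slot_h, is_breakfast in ((7.5, True), (12.5, False), (18.5, False)):
            if is_breakfast and d in mtt_days:
                continue
            jitter = rng.uniform(-30.0, 30.0)
            when = datetime(d.year, d.month, d.day, tzinfo=tz) + timedelta(
                hours=slot_h, minutes=float(jitter)
            )
            carbs = float(np.clip(rng.normal(60.0, 12.0), 15.0, 120.0))
            meals.append((when, MealResponseParams(carbs_g=carbs)))
    return meals


def simulate_study(
    n_subjects: int = 6,
    seed: int | None = 0,
    start: datetime = datetime(2018, 3, 5, 0, 0, tzinfo=STUDY_TZ),
    effect_multiplier: float = 0.7,
    period_days: int = 14,
    washout_days: int = 4,
    trace_params: TraceGenParams | None = None,
    scan_params: ScanBehaviorParams | None = None,
    drop_mtt_for: tuple[str, ...] = (),
) -> StudyBundle:
    """Generate a full 2x2 cross-over cohort.

    Each subject carries the sensor from two days before period 1 to one day
    after period 2, eats three jittered meals a day, performs four fasted MTTs
    (45-g standard drink at 07:00 local, breakfast skipped) at the beginning
    and end of each period, and annotates meals and MTTs through the app.  The
    end-of-product MTT response is scaled by ``effect_multiplier`` (< 1 means
    the product blunts the excursion).  Subjects named in ``drop_mtt_for``
    omit one MTT annotation, yielding incomplete subjects downstream.
    """
    if trace_params is None:
        trace_params = TraceGenParams()
    if scan_params is None:
        scan_params = ScanBehaviorParams()
    master = np.random.default_rng(seed)
    tz = start.tzinfo or STUDY_TZ

    traces: dict[str, GlucoseTrace] = {}
    designs: dict[str, StudyDesign] = {}
    scan_times: dict[str, list[datetime]] = {}
    events: list[AnnotationEvent] = []
    truth: dict = {"effect_multiplier": effect_multiplier, "subjects": {}}

    for i in range(n_subjects):
        sid = f"S{i + 1}"
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        first_arm = Arm.PRODUCT if i % 2 == 0 else Arm.PLACEBO
        second_arm = Arm.PLACEBO if first_arm is Arm.PRODUCT else Arm.PRODUCT
        p1 = StudyPeriod(first_arm, start, start + timedelta(days=period_days))
        w_end = p1.end + timedelta(days=washout_days)
        p2 = StudyPeriod(second_arm, w_end, w_end + timedelta(days=period_days))
        design = StudyDesign(
            subject_id=sid, periods=(p1, p2), washouts=((p1.end, w_end),)
        )

        trace_start = start - timedelta(days=2)
        trace_end = p2.end + timedelta(days=1)
        n_days = int((trace_end - trace_start) / timedelta(days=1))
        day_list = [
            (trace_start + timedelta(days=k)).date() for k in range(n_days)
        ]

        # four MTTs: 07:00 local on the first and last full day of each period
        mtt_times = []
        for p in (p1, p2):
            for d in (p.start.date(), (p.end - timedelta(days=1)).date()):
                mtt_times.append(
                    datetime(d.year, d.month, d.day, 7, 0, tzinfo=tz)
                )
        mtt_days = {t.date() for t in mtt_times}

        meals = _meal_schedule(day_list, mtt_days, rng, tz)
        height = float(np.clip(rng.normal(1.2, 0.2), 0.4, None))
        subject_mtts = []
        for t in mtt_times:
            in_product = design.period_for_arm(Arm.PRODUCT)
            is_product_end = (
                in_product.start <= t <= in_product.end
                and t.date() == (in_product.end - timedelta(days=1)).date()
            )
            mult = effect_multiplier if is_product_end else 1.0
            subject_mtts.append((t, mult))
            meals.append(
                (
                    t,
                    MealResponseParams(
                        carbs_g=45.0, peak_height_per_g=height * mult
                    ),
                )
            )

        sp = TraceGenParams(
            baseline_mean=trace_params.baseline_mean,
            baseline_sd_between_subject=trace_params.baseline_sd_between_subject,
            circadian_amplitude=trace_params.circadian_amplitude,
            noise_sd=trace_params.noise_sd,
            noise_autocorr=trace_params.noise_autocorr,
            sampling_interval_min=trace_params.sampling_interval_min,
        )
        trace = simulate_trace(
            sp,
            duration_days=n_days,
            meals=tuple(sorted(meals, key=lambda m: m[0])),
            subject_id=sid,
            start=trace_start,
            rng=rng,
        )

        for t, _ in subject_mtts:
            if sid in drop_mtt_for and t == mtt_times[-1]:
                continue
            events.append(
                AnnotationEvent(sid, t, EventKind.MTT_START, payload="standard drink")
            )
        for when, mp in meals:
            if when in {t for t, _ in subject_mtts}:
                continue
            events.append(
                AnnotationEvent(sid, when, EventKind.MEAL, payload=f"{mp.carbs_g:.0f} g")
            )
        # sparse fingerstick cross-checks
        t_epoch = trace.times_epoch()
        vals = trace.values()
        for k in range(0, n_days, 3):
            when = datetime.combine(
                day_list[k], datetime.min.time(), tzinfo=tz
            ) + timedelta(hours=20)
            idx = int(np.argmin(np.abs(t_epoch - when.timestamp())))
            fs = float(np.clip(vals[idx] + rng.normal(0.0, 5.0), 41.0, 494.0))
            events.append(
                AnnotationEvent(
                    sid, when, EventKind.FINGERSTICK, payload="", value=round(fs, 1)
                )
            )

        traces[sid] = trace
        designs[sid] = design
        scans = simulate_scan_times(
            ScanBehaviorParams(
                median_interval_h=scan_params.median_interval_h,
                fatigue_drift=scan_params.fatigue_drift,
                overshoot_prob=scan_params.overshoot_prob,
                interval_log_sd=scan_params.interval_log_sd,
                buffer_h=scan_params.buffer_h,
            ),
            trace.start,
            trace.end,
            rng=rng,
        )
        scan_times[sid] = scans
        truth["subjects"][sid] = {
            "first_arm": first_arm.value,
            "mtt_times": [t.isoformat() for t, _ in subject_mtts],
            "mtt_multipliers": [m for _, m in subject_mtts],
            "meal_times": [w.isoformat() for w, _ in meals],
        }

    events.sort(key=lambda e: (e.subject_id, e.timestamp))
    return StudyBundle(
        traces=traces,
        events=events,
        designs=designs,
        scan_times=scan_times,
        truth=truth,
    )
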