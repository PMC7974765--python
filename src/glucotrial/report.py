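"""End-to-end study report: one structured JSON document per cohort.

Wires the modules together: label each subject's four MTT annotations from the
cross-over design, compute incremental AUCs and the dAUC/ddAUC contrasts, run
peak detection with annotation matching, compliance metrics, and consensus
glucose metrics, then the cohort-level one-sided signed-rank test, baseline
stratification, and (optionally) a simulation-based power estimate for a
future design.  Subjects lacking one of the four MTTs are flagged incomplete
and excluded from the cohort test; the report is still produced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from . import compliance as comp
from . import metrics as met
from . import mtt as mtt_mod
from . import peaks as peaks_mod
from .core import (
    AnnotationEvent,
    Arm,
    EventKind,
    GlucoseTrace,
    InsufficientDataError,
    StudyDesign,
)
from .mtt import (
    AUCConvention,
    IncompleteSubjectError,
    MTTLabel,
    MTTResult,
)

__all__ = ["ReportConfig", "run_study_report", "label_mtt_events", "report_to_json"]

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class ReportConfig:
    auc_convention: str = "positive_only"
    alpha: float = 0.05
    alternative: str = "less"
    baseline_cutoff: float = 1000.0  # (mg/dL)*min
    fasting_hours: float = 6.0
    excursion_limit: float = 25.0
    power_n_subjects: int = 35
    power_n_sim: int = 0  # 0 disables the power estimate
    seed: int = 0


def label_mtt_events(
    events: Sequence[AnnotationEvent],
    design: StudyDesign,
) -> tuple[dict[MTTLabel, datetime], list[str]]:
    """Assign the four MTT labels from mtt_start annotations and the design.

    For each period, MTT annotations falling in [period start - 1 day, period
    end] are considered; the earliest is the beginning test, the latest the
    end test.  Returns the labelling plus a list of problems (missing labels).
    """
    starts = sorted(
        e.timestamp for e in events if e.kind is EventKind.MTT_START
    )
    labels: dict[MTTLabel, datetime] = {}
    problems: list[str] = []
    for period in design.periods:
        arm = period.arm.value
        window = [
            t
            for t in starts
            if period.start - timedelta(days=1) <= t <= period.end
        ]
        begin_lab = MTTLabel(f"begin_{arm}")
        end_lab = MTTLabel(f"end_{arm}")
        if not window:
            problems.append(f"no MTT annotation in the {arm} period")
            continue
        labels[begin_lab] = window[0]
        if len(window) >= 2:
            labels[end_lab] = window[-1]
        else:
            problems.append(f"only one MTT annotation in the {arm} period")
    for lab in MTTLabel:
        if lab not in labels and not any(lab.value.endswith(p.arm.value) for p in design.periods):
            problems.append(f"design has no period for {lab.value}")
    return labels, problems


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, (datetime, date)):
        return obj.isoformat()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(x) for x in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and obj != obj:  # NaN is not valid JSON
        return None
    return obj


def _subject_block(
    trace: GlucoseTrace,
    events: list[AnnotationEvent],
    design: StudyDesign,
    config: ReportConfig,
    scan_times,
) -> dict:
    block: dict = {"subject_id": trace.subject_id, "complete": False, "problems": []}
    labels, problems = label_mtt_events(events, design)
    block["problems"].extend(problems)

    detected = peaks_mod.detect_peaks(trace)
    match = peaks_mod.match_peaks_to_events(detected, events)
    summary = peaks_mod.peak_summaries(trace, detected)
    block["peaks"] = {
        "n_peaks": len(detected),
        "intervals": detected,
        "daily_summary": summary,
        "n_meals_matched": len(match.matches),
        "n_meals_unmatched": len(match.unmatched_events),
    }

    mtt_results: list[MTTResult] = []
    mtt_blocks = {}
    for lab, t0 in sorted(labels.items(), key=lambda kv: kv[1]):
        fasting = comp.fasting_precheck(
            trace,
            t0,
            fasting_hours=config.fasting_hours,
            excursion_limit=config.excursion_limit,
            peaks=detected,
        )
        try:
            res = mtt_mod.incremental_auc(
                trace,
                t0,
                convention=AUCConvention(config.auc_convention),
                label=lab,
            )
            mtt_results.append(res)
            mtt_blocks[lab.value] = {"result": res, "fasting": fasting}
        except (InsufficientDataError, ValueError) as exc:
            block["problems"].append(f"{lab.value}: {exc}")
    block["mtt"] = mtt_blocks

    try:
        contrast = mtt_mod.crossover_contrasts(mtt_results, design)
        block["contrast"] = {
            "delta_auc_placebo": contrast.delta_auc_placebo,
            "delta_auc_product": contrast.delta_auc_product,
            "delta_delta_auc": contrast.delta_delta_auc,
        }
        first_label = min(labels, key=lambda k: labels[k], default=None)
        block["baseline_auc"] = next(
            r.auc for r in mtt_results if r.label is first_label
        )
        block["complete"] = True
    except (IncompleteSubjectError, StopIteration):
        block["contrast"] = None
        block["baseline_auc"] = None

    span_days = max(
        1, int((design.periods[-1].end - design.periods[0].start) / timedelta(days=1))
    )
    block["compliance"] = {
        "annotations": comp.annotation_rate_stats(
            events, span_days, start=design.periods[0].start
        ),
        "scan_gaps": comp.scan_gap_stats(scan_times) if scan_times else None,
    }
    block["glucose_metrics"] = {
        "summary": met.subject_summary(trace),
        "time_in_range": met.time_in_range(trace),
        "hypo_episodes": met.hypoglycemic_episodes(trace),
    }
    return block


def run_study_report(
    traces: Mapping[str, GlucoseTrace],
    events: Sequence[AnnotationEvent],
    designs: Mapping[str, StudyDesign],
    config: ReportConfig | None = None,
    scan_times: Mapping[str, list[datetime]] | None = None,
) -> dict:
    """Build the full study report as a JSON-serializable dict.

    Deterministic for fixed inputs and config: no wall-clock timestamps are
    embedded, subjects appear in sorted order.
    """
    if config is None:
        config = ReportConfig()
    subjects = {}
    for sid in sorted(traces):
        if sid not in designs:
            raise KeyError(f"no design for subject {sid}")
        evs = [e for e in events if e.subject_id == sid]
        subjects[sid] = _subject_block(
            traces[sid],
            evs,
            designs[sid],
            config,
            (scan_times or {}).get(sid),
        )

    complete = [s for s in subjects.values() if s["complete"]]
    dd = [s["contrast"]["delta_delta_auc"] for s in complete]
    cohort: dict = {
        "n_subjects": len(subjects),
        "n_complete": len(complete),
        "delta_delta_auc": dd,
    }
    if any(v != 0 for v in dd):
        cohort["signed_rank"] = mtt_mod.exact_wilcoxon_signed_rank(
            dd, alternative=config.alternative
        )
    else:
        cohort["signed_rank"] = None
    baselines = {
        s["subject_id"]: s["baseline_auc"] for s in complete if s["baseline_auc"] is not None
    }
    vals = list(baselines.values())
    if len(vals) >= 2 and min(vals) < config.baseline_cutoff < max(vals):
        cohort["stratification"] = mtt_mod.stratify_by_baseline_auc(
            baselines, cutoff=config.baseline_cutoff
        )
    else:
        cohort["stratification"] = None
    if config.power_n_sim > 0 and len(dd) >= 2:
        negatives = [v for v in dd if v < 0] or dd
        sd = float(np.std(dd, ddof=1))
        if sd > 0:
            cohort["power"] = mtt_mod.power_by_simulation(
                effect_mean=float(np.mean(negatives)),
                effect_sd=sd,
                n_subjects=config.power_n_subjects,
                alpha=config.alpha,
                alternative=config.alternative,
                n_sim=config.power_n_sim,
                seed=config.seed,
            )
        else:
            cohort["power"] = None
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": config,
        "subjects": subjects,
        "cohort": cohort,
    }
    return _jsonify(report)


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, sort_keys=True)
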