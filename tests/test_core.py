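"""Domain types, file parsing, and trace reconstruction from scan downloads."""

from __future__ import annotations

from datetime import timedelta

import pytest

from glucotrial.core import (
    AnnotationEvent,
    EventKind,
    GlucoseSample,
    GlucoseTrace,
    IntegrityError,
    ParseError,
    ScanDownload,
    StudyDesign,
    StudyPeriod,
    Arm,
    merge_scan_downloads,
    parse_design,
    parse_events,
    parse_trace_table,
    slice_window,
)
from glucotrial.synth import (
    ScanBehaviorParams,
    TraceGenParams,
    downloads_from_scan_times,
    simulate_scan_records,
    simulate_trace,
)

from conftest import T0, make_trace


# ---------------------------------------------------------------------------
# Samples, traces, and design invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("bad", [0.0, -5.0, 500.0, 620.0])
def test_sample_rejects_implausible_glucose(bad):
    with pytest.raises(IntegrityError):
        GlucoseSample(T0, bad)


def test_trace_requires_strictly_increasing_timestamps():
    s = GlucoseSample(T0, 100.0)
    with pytest.raises(IntegrityError):
        GlucoseTrace(subject_id="S1", samples=(s, s))


def test_event_value_present_iff_fingerstick():
    AnnotationEvent("S1", T0, EventKind.FINGERSTICK, value=98.0)  # fine
    with pytest.raises(IntegrityError):
        AnnotationEvent("S1", T0, EventKind.MEAL, value=98.0)
    with pytest.raises(IntegrityError):
        AnnotationEvent("S1", T0, EventKind.FINGERSTICK, value=None)


def test_design_rejects_out_of_bounds_periods():
    ok = StudyPeriod(Arm.PRODUCT, T0, T0 + timedelta(days=14))
    with pytest.raises(IntegrityError):
        StudyDesign("S1", periods=(StudyPeriod(Arm.PLACEBO, T0, T0 + timedelta(days=2)),))
    with pytest.raises(IntegrityError):  # washout too long
        StudyDesign(
            "S1",
            periods=(ok,),
            washouts=((ok.end, ok.end + timedelta(days=10)),),
        )


# ---------------------------------------------------------------------------
# CSV / JSON parsing
# ---------------------------------------------------------------------------


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_parse_trace_table_roundtrip_and_sorting(tmp_path):
    path = _write(
        tmp_path,
        "t.csv",
        "subject_id,timestamp,glucose_mgdl,source\n"
        "S1,2018-03-20T00:30:00-08:00,102,cgm_scan\n"
        "S1,2018-03-20T00:00:00-08:00,100,cgm_scan\n"
        "S2,2018-03-20T00:00:00-08:00,90,cgm_scan\n"
        "S1,2018-03-20T00:15:00-08:00,101,cgm_scan\n",
    )
    trace = parse_trace_table(path, "S1")
    assert len(trace) == 3  # other subject ignored
    assert [s.glucose for s in trace] == [100.0, 101.0, 102.0]  # sorted ascending


def test_parse_trace_table_errors(tmp_path):
    bad_ts = _write(
        tmp_path,
        "a.csv",
        "subject_id,timestamp,glucose_mgdl,source\nS1,not-a-time,100,cgm_scan\n",
    )
    with pytest.raises(ParseError, match="row 2"):
        parse_trace_table(bad_ts, "S1")
    conflict = _write(
        tmp_path,
        "b.csv",
        "subject_id,timestamp,glucose_mgdl,source\n"
        "S1,2018-03-20T00:00:00-08:00,100,cgm_scan\n"
        "S1,2018-03-20T00:00:00-08:00,101,cgm_scan\n",
    )
    with pytest.raises(IntegrityError):
        parse_trace_table(conflict, "S1")
    out_of_bounds = _write(
        tmp_path,
        "c.csv",
        "subject_id,timestamp,glucose_mgdl,source\nS1,2018-03-20T00:00:00-08:00,900,cgm_scan\n",
    )
    with pytest.raises(IntegrityError):
        parse_trace_table(out_of_bounds, "S1")


def test_parse_events_csv_and_json_agree(tmp_path):
    csv_path = _write(
        tmp_path,
        "e.csv",
        "subject_id,timestamp,kind,payload,value\n"
        "S1,2018-03-20T07:00:00-08:00,mtt_start,drink,\n"
        "S1,2018-03-20T12:00:00-08:00,meal,lunch,\n"
        "S1,2018-03-20T20:00:00-08:00,fingerstick,,97.0\n",
    )
    json_path = _write(
        tmp_path,
        "e.json",
        '[{"subject_id": "S1", "timestamp": "2018-03-20T07:00:00-08:00",'
        ' "kind": "mtt_start", "payload": "drink", "value": null},'
        '{"subject_id": "S1", "timestamp": "2018-03-20T12:00:00-08:00",'
        ' "kind": "meal", "payload": "lunch", "value": null},'
        '{"subject_id": "S1", "timestamp": "2018-03-20T20:00:00-08:00",'
        ' "kind": "fingerstick", "payload": "", "value": 97.0}]',
    )
    from_csv = parse_events(csv_path, "S1")
    from_json = parse_events(json_path, "S1")
    assert from_csv == from_json
    assert [e.kind for e in from_csv] == [
        EventKind.MTT_START,
        EventKind.MEAL,
        EventKind.FINGERSTICK,
    ]
    assert from_csv[-1].value == 97.0


def test_parse_design_roundtrip(tmp_path):
    path = _write(
        tmp_path,
        "d.json",
        '{"subject_id": "S1", "periods": ['
        '{"arm": "product", "start": "2018-03-05T00:00:00-08:00", "end": "2018-03-19T00:00:00-08:00"},'
        '{"arm": "placebo", "start": "2018-03-23T00:00:00-08:00", "end": "2018-04-06T00:00:00-08:00"}],'
        '"washouts": [{"start": "2018-03-19T00:00:00-08:00", "end": "2018-03-23T00:00:00-08:00"}]}',
    )
    design = parse_design(path)
    assert design.periods[0].arm is Arm.PRODUCT
    assert design.period_for_arm(Arm.PLACEBO).duration == timedelta(days=14)


# ---------------------------------------------------------------------------
# merge_scan_downloads
# ---------------------------------------------------------------------------


def test_merge_overlapping_downloads_dedupes():
    trace = make_trace([100 + i for i in range(33)])  # 8 h at 15 min
    scans = [T0 + timedelta(hours=4), T0 + timedelta(hours=8)]
    downloads = downloads_from_scan_times(trace, scans)
    merged = merge_scan_downloads(downloads, subject_id="S1")
    # windows overlap by 4 h; the union covers the whole trace, no duplicates
    assert len(merged.trace) == 33
    assert merged.gaps == ()


def test_merge_reports_gap_for_nine_hour_spacing():
    # scans at 0 h and 9 h with an 8-h buffer: (0 h, 1 h] never downloaded
    trace = make_trace([100.0] * 37)  # T0 .. T0+9h
    scans = [T0, T0 + timedelta(hours=9)]
    merged = merge_scan_downloads(downloads_from_scan_times(trace, scans), "S1")
    assert merged.gaps == ((T0, T0 + timedelta(hours=1)),)
    missing = [
        T0 + timedelta(minutes=15 * k) for k in range(1, 5)
    ]  # the four samples at 00:15 .. 01:00 aged out before the second scan
    got = {s.timestamp for s in merged.trace.samples}
    for t in missing:
        assert t not in got
    assert len(merged.trace) == 37 - 4


def test_merge_single_download_is_identity():
    trace = make_trace([100.0, 110.0, 120.0])
    dl = downloads_from_scan_times(trace, [trace.end])
    merged = merge_scan_downloads(dl, "S1")
    assert merged.trace.samples == trace.samples


def test_merge_conflicting_values_raise():
    a = ScanDownload(T0 + timedelta(hours=1), (GlucoseSample(T0 + timedelta(minutes=30), 100.0),))
    b = ScanDownload(T0 + timedelta(hours=2), (GlucoseSample(T0 + timedelta(minutes=30), 105.0),))
    with pytest.raises(IntegrityError):
        merge_scan_downloads([a, b])


def test_merge_is_idempotent():
    trace = make_trace([95.0 + (i % 7) for i in range(97)])
    scans = [T0 + timedelta(hours=h) for h in (6, 12, 18, 24.5)]
    merged = merge_scan_downloads(downloads_from_scan_times(trace, scans), "S1")
    again = merge_scan_downloads(
        downloads_from_scan_times(merged.trace, scans), "S1"
    )
    assert again.trace.samples == merged.trace.samples


def test_no_loss_when_scans_within_buffer():
    params = TraceGenParams(seed=11)
    trace = simulate_trace(params, 3.0)
    downloads = simulate_scan_records(
        ScanBehaviorParams(
            median_interval_h=6.0, fatigue_drift=1.0, overshoot_prob=0.0,
            interval_log_sd=0.0, seed=5,
        ),
        trace,
    )
    merged = merge_scan_downloads(downloads, trace.subject_id)
    assert len(merged.trace) == len(trace)
    assert merged.gaps == ()


# ---------------------------------------------------------------------------
# slice_window
# ---------------------------------------------------------------------------


def test_two_hour_slice_on_grid_has_nine_samples():
    trace = make_trace([100.0] * 96)  # one day
    window = slice_window(trace, T0, T0 + timedelta(hours=2))
    assert len(window) == 9  # closed-interval convention


def test_slice_outside_span_is_empty_and_full_span_is_identity():
    trace = make_trace([100.0, 101.0, 102.0])
    empty = slice_window(trace, T0 + timedelta(days=2), T0 + timedelta(days=3))
    assert len(empty) == 0
    full = slice_window(trace, trace.start, trace.end)
    assert full.samples == trace.samples
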