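from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest

from glucotrial.core import GlucoseSample, GlucoseTrace, SampleSource

TZ = timezone(timedelta(hours=-8))
T0 = datetime(2018, 3, 20, 0, 0, tzinfo=TZ)

# Printed cross-over contrast table of the six-subject pilot:
# subject -> (baseline AUC, dAUC placebo, dAUC product, ddAUC), (mg/dL)*min
TABLE1 = {
    "6": (265.3, 1035.1, 1683.2, 648.1),
    "3": (737.0, 1027.1, 1598.3, 571.2),
    "5": (834.8, 102.8, 552.8, 450.0),
    "4": (1557.6, 427.7, -933.0, -1360.7),
    "1": (2084.2, -221.6, -1213.9, -992.3),
    "2": (3931.8, 1309.1, -978.1, -2287.2),
}


def make_trace(
    values,
    start: datetime = T0,
    interval_min: float = 15.0,
    subject_id: str = "S1",
) -> GlucoseTrace:
    """Trace on a regular grid from a plain list of glucose values."""
    step = timedelta(minutes=interval_min)
    samples = tuple(
        GlucoseSample(start + i * step, float(v), SampleSource.CGM_SCAN)
        for i, v in enumerate(values)
    )
    return GlucoseTrace(subject_id=subject_id, samples=samples, nominal_interval=step)


@pytest.fixture
def table1():
    return TABLE1
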