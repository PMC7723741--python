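import pandas as pd
import pytest

from tempheno import EventRecord, EventStream, Instant, Interval, PatientAttributes

T0 = pd.Timestamp("2024-01-01 00:00")
H = pd.Timedelta(hours=1)


def hours(k: float) -> pd.Timestamp:
    return T0 + k * H


def instant(concept, t, value=None, unit=None, pid="p1"):
    """Instant at a numeric time (unit-free timeline)."""
    return Instant(pid, concept, t, value, unit)


def interval(start, end, concept="iv", pid="p1", kind="bounded"):
    return Interval(pid, concept, start, end, kind)


def stream(rows, attrs=None):
    """Build a stream from (pid, concept, time, value, unit) tuples."""
    events = [EventRecord(*((r + (None, None))[:5])) for r in rows]
    attributes = {
        pid: PatientAttributes(pid, a) for pid, a in (attrs or {}).items()
    }
    return EventStream(events=events, attributes=attributes)


@pytest.fixture
def icu_stream():
    """One patient: a 10-day stay with a high lactate on day 2."""
    rows = [
        ("p1", "icu_admit", hours(0)),
        ("p1", "icu_discharge", hours(240)),
        ("p1", "lactate", hours(48), 3.1, "mmol/L"),
        ("p1", "lactate", hours(96), 1.2, "mmol/L"),
    ]
    return stream(rows, attrs={"p1": {"body_weight": 70.0, "sex": "F", "age": 61}})
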