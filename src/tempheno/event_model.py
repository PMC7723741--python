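"""Core data model for timestamped clinical events.

The unit of raw data is the :class:`EventRecord`: one observation for one
patient — a lab result, a vital-sign measurement, a drug administration, an
admission or discharge. Temporal abstraction distinguishes two kinds of
temporal entity built from these records:

* an :class:`Instant` — a clinical event with a single timestamp and no
  duration (one lactate result, one antibiotic dose);
* an :class:`Interval` — a clinical event with a start and an end and a
  strictly positive duration (a hospitalization, a hypothermia episode).

Files are long-format CSV; timestamps are ISO-8601 and are converted to a
single internal representation (:class:`pandas.Timestamp`). All times are
assumed to be on one clock — no timezone arithmetic is performed. For
testing and enumeration, plain numbers are also accepted as times; the
model only requires that times be totally ordered and subtractable.

Intervals are closed at both ends, ``[start, end]``: an instant whose
timestamp equals an interval boundary lies inside the interval. This one
convention is applied everywhere (abstraction, relations, within-interval
aggregation) so that boundary cases have a single answer.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import FormatError, PreconditionError, RowError

__all__ = [
    "DEFAULT_DIALECT",
    "CohortResult",
    "EventRecord",
    "EventStream",
    "EvidenceSpan",
    "Instant",
    "Interval",
    "PatientAttributes",
    "PatientResult",
    "Verdict",
    "parse_duration",
    "parse_time",
    "read_attributes",
    "read_cohort",
    "read_events",
    "select",
    "write_attributes",
    "write_cohort",
    "write_events",
]

#: Default column names of the long-format event table.
DEFAULT_DIALECT: dict[str, str] = {
    "patient_id": "patient_id",
    "concept": "concept",
    "time": "time",
    "value": "value",
    "unit": "unit",
}


def parse_time(raw):
    """Parse an ISO-8601 timestamp string into the internal representation.

    Numbers pass through unchanged (convenient for synthetic timelines and
    exhaustive enumeration tests).
    """
    if isinstance(raw, numbers.Real) and not isinstance(raw, bool):
        return raw
    ts = pd.Timestamp(raw)
    if pd.isna(ts):
        raise ValueError(f"unparseable timestamp: {raw!r}")
    return ts


def parse_duration(raw):
    """Parse a duration: ``pandas.Timedelta`` strings like ``'6h'`` or
    ``'7 days'``, or plain numbers (unit-free timelines)."""
    if isinstance(raw, numbers.Real) and not isinstance(raw, bool):
        return raw
    if isinstance(raw, pd.Timedelta):
        return raw
    td = pd.Timedelta(raw)
    if pd.isna(td):
        raise ValueError(f"unparseable duration: {raw!r}")
    return td


def _parse_value(raw):
    """Values are numeric quantities or categorical tokens; '' means absent."""
    if raw is None:
        return None
    if isinstance(raw, numbers.Real) and not isinstance(raw, bool):
        return float(raw)
    text = str(raw).strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        return text


@dataclass(frozen=True)
class EventRecord:
    """One timestamped clinical observation."""

    patient_id: str
    concept: str
    time: object
    value: float | str | None = None
    unit: str | None = None

    def as_instant(self) -> "Instant":
        return Instant(self.patient_id, self.concept, self.time, self.value, self.unit)


@dataclass(frozen=True)
class Instant:
    """A zero-duration clinical event: exactly one timestamp.

    ``transformed`` optionally carries the value after an external-variable
    transform (e.g. urine output divided by body weight); the original
    ``value`` is always preserved alongside it.
    """

    patient_id: str
    concept: str
    time: object
    value: float | str | None = None
    unit: str | None = None
    transformed: float | None = None


class IntervalKind(str, Enum):
    INSTANT_BASED = "instant_based"
    BOUNDED = "bounded"
    MOVING_WINDOW = "moving_window"


@dataclass
class Interval:
    """A clinical event with a start, an end, and positive duration.

    ``attributes`` holds derived values (``duration``, ``count``,
    ``total_dose`` …); ``support`` records the source instants the interval
    was abstracted from, every one of which lies within ``[start, end]``.
    """

    patient_id: str
    concept: str
    start: object
    end: object
    kind: IntervalKind
    attributes: dict = field(default_factory=dict)
    support: tuple = ()

    def __post_init__(self):
        if not self.end > self.start:
            raise PreconditionError(
                f"interval requires end > start, got [{self.start}, {self.end}]"
            )
        for inst in self.support:
            if not (self.start <= inst.time <= self.end):
                raise PreconditionError(
                    f"supporting instant at {inst.time} outside [{self.start}, {self.end}]"
                )
        if isinstance(self.kind, str):
            self.kind = IntervalKind(self.kind)

    @property
    def duration(self):
        return self.end - self.start


@dataclass(frozen=True)
class PatientAttributes:
    """Non-temporal attributes of one patient (age, sex, body weight …)."""

    patient_id: str
    attributes: Mapping[str, object] = field(default_factory=dict)
    units: Mapping[str, str] = field(default_factory=dict)

    def get(self, name: str, default=None):
        return self.attributes.get(name, default)


@dataclass
class EventStream:
    """A collection of event records plus per-patient attributes.

    Iteration per patient yields events in non-decreasing time order;
    records with identical timestamps keep their input order (two drug
    boluses in the same minute are both retained, in the order charted).
    """

    events: list[EventRecord] = field(default_factory=list)
    attributes: dict[str, PatientAttributes] = field(default_factory=dict)
    validation: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.attributes = {
            (a.patient_id if isinstance(a, PatientAttributes) else k): a
            if isinstance(a, PatientAttributes)
            else PatientAttributes(k, a)
            for k, a in (
                self.attributes.items()
                if isinstance(self.attributes, dict)
                else ((a.patient_id, a) for a in self.attributes)
            )
        }
        self._sort()

    def _sort(self):
        # stable sort: ties keep input order (duplicate timestamps allowed)
        self.events.sort(key=lambda e: (e.patient_id, _sort_key(e.time)))

    @property
    def patient_ids(self) -> list[str]:
        seen = dict.fromkeys(e.patient_id for e in self.events)
        seen.update(dict.fromkeys(self.attributes))
        return list(seen)

    @property
    def concepts(self) -> set[str]:
        return {e.concept for e in self.events}

    def events_for(self, patient_id: str) -> list[EventRecord]:
        return [e for e in self.events if e.patient_id == patient_id]

    def attributes_for(self, patient_id: str) -> PatientAttributes:
        return self.attributes.get(patient_id, PatientAttributes(patient_id, {}))

    def iter_patients(self) -> Iterator[tuple[str, list[EventRecord]]]:
        for pid in self.patient_ids:
            yield pid, self.events_for(pid)

    def restrict(self, patient_ids: Iterable[str]) -> "EventStream":
        keep = set(patient_ids)
        return EventStream(
            events=[e for e in self.events if e.patient_id in keep],
            attributes={p: a for p, a in self.attributes.items() if p in keep},
        )


def _sort_key(t):
    # pandas Timestamps and numbers never mix within one stream in practice;
    # normalise to a comparable scalar just in case
    if isinstance(t, pd.Timestamp):
        return t.value
    return t


# ---------------------------------------------------------------------------
# readers / writers


def read_events(
    path,
    dialect: Mapping[str, str] | None = None,
    attributes_path=None,
    policy: str = "strict",
) -> EventStream:
    """Read a long-format event table (CSV) into a validated stream.

    Parameters
    ----------
    dialect:
        Maps the canonical field names (``patient_id, concept, time, value,
        unit``) to the file's column names. Defaults to the canonical names.
    policy:
        ``"strict"`` — any malformed row raises :class:`RowError` naming the
        row; ``"collect"`` — malformed rows are dropped and reported in
        ``stream.validation``.

    Duplicated identical rows are retained (real ICU charts contain genuine
    collisions) but flagged in the validation report.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    if policy not in ("strict", "collect"):
        raise ValueError(f"unknown policy: {policy!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [dialect["patient_id"], dialect["concept"], dialect["time"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    events: list[EventRecord] = []
    report: list[str] = []
    seen_rows: dict[tuple, int] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            time = parse_time(row[dialect["time"]])
        except ValueError as exc:
            if policy == "strict":
                raise RowError(idx, str(exc)) from None
            report.append(f"row {idx}: dropped ({exc})")
            continue
        value = _parse_value(row.get(dialect["value"]))
        unit = str(row.get(dialect["unit"], "")).strip() or None
        rec = EventRecord(
            patient_id=str(row[dialect["patient_id"]]),
            concept=str(row[dialect["concept"]]),
            time=time,
            value=value,
            unit=unit,
        )
        key = (rec.patient_id, rec.concept, str(rec.time), rec.value, rec.unit)
        if key in seen_rows:
            report.append(
                f"row {idx}: duplicate of row {seen_rows[key]} "
                f"({rec.patient_id}/{rec.concept}@{rec.time}); retained"
            )
        else:
            seen_rows[key] = idx
        events.append(rec)

    attributes = {}
    if attributes_path is not None:
        attributes = read_attributes(attributes_path)
    stream = EventStream(events=events, attributes=attributes)
    stream.validation = report
    return stream


def write_events(stream: EventStream, path, dialect: Mapping[str, str] | None = None) -> None:
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    rows = [
        {
            dialect["patient_id"]: e.patient_id,
            dialect["concept"]: e.concept,
            dialect["time"]: _fmt_time(e.time),
            dialect["value"]: "" if e.value is None else e.value,
            dialect["unit"]: e.unit or "",
        }
        for e in stream.events
    ]
    pd.DataFrame(rows, columns=list(dialect.values())).to_csv(path, index=False)


def read_attributes(path) -> dict[str, PatientAttributes]:
    """Read the per-patient attribute table: ``patient_id, name, value, unit``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("patient_id", "name", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: dict[str, dict] = {}
    units: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        out.setdefault(pid, {})[row.name] = _parse_value(row.value)
        if getattr(row, "unit", ""):
            units.setdefault(pid, {})[row.name] = row.unit
    return {
        pid: PatientAttributes(pid, attrs, units.get(pid, {}))
        for pid, attrs in out.items()
    }


def write_attributes(attributes: Mapping[str, PatientAttributes], path) -> None:
    rows = []
    for pid in attributes:
        pa = attributes[pid]
        for name, value in pa.attributes.items():
            rows.append(
                {
                    "patient_id": pid,
                    "name": name,
                    "value": value,
                    "unit": pa.units.get(name, ""),
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "name", "value", "unit"]).to_csv(
        path, index=False
    )


def _fmt_time(t) -> str:
    if isinstance(t, pd.Timestamp):
        return t.isoformat()
    return repr(t) if not isinstance(t, (int, float)) else str(t)


# ---------------------------------------------------------------------------
# selection


def select(
    stream: EventStream, concept: str, patient: str | None = None
) -> list[Instant]:
    """All events of one concept (optionally one patient), as time-ordered
    instants. An unknown concept yields an empty list, not an error."""
    return [
        e.as_instant()
        for e in stream.events
        if e.concept == concept and (patient is None or e.patient_id == patient)
    ]


# ---------------------------------------------------------------------------
# cohort results


class Verdict(str, Enum):
    MATCHED = "matched"
    NOT_MATCHED = "not_matched"
    ERROR = "error"


@dataclass(frozen=True)
class EvidenceSpan:
    """One matched entity, flattened to a labelled span.

    Instants serialise with ``start == end``.
    """

    label: str
    start: object
    end: object


@dataclass
class PatientResult:
    patient_id: str
    verdict: Verdict
    evidence: tuple[EvidenceSpan, ...] = ()
    reason: str | None = None


@dataclass
class CohortResult:
    """Per-patient match verdicts with the evidence that produced them.

    Every patient present in the evaluated stream appears exactly once.
    Patients whose evaluation failed (e.g. a missing body weight needed by
    the phenotype) carry an ``error`` verdict and are excluded from both
    the matched and unmatched counts.
    """

    results: dict[str, PatientResult] = field(default_factory=dict)

    @property
    def matched(self) -> set[str]:
        return {p for p, r in self.results.items() if r.verdict is Verdict.MATCHED}

    @property
    def unmatched(self) -> set[str]:
        return {p for p, r in self.results.items() if r.verdict is Verdict.NOT_MATCHED}

    @property
    def errors(self) -> set[str]:
        return {p for p, r in self.results.items() if r.verdict is Verdict.ERROR}

    def __getitem__(self, patient_id: str) -> PatientResult:
        return self.results[patient_id]

    def __len__(self) -> int:
        return len(self.results)


def write_cohort(result: CohortResult, path) -> None:
    """Write a cohort result: one row per patient per evidence span.

    Columns: ``patient_id, matched, evidence_start, evidence_end,
    evidence_label``. Patients without evidence still get one row so the
    full cohort accounting round-trips.
    """
    rows = []
    for pid, res in result.results.items():
        if res.evidence:
            for span in res.evidence:
                rows.append(
                    {
                        "patient_id": pid,
                        "matched": res.verdict.value,
                        "evidence_start": _fmt_time(span.start),
                        "evidence_end": _fmt_time(span.end),
                        "evidence_label": span.label,
                    }
                )
        else:
            rows.append(
                {
                    "patient_id": pid,
                    "matched": res.verdict.value,
                    "evidence_start": "",
                    "evidence_end": "",
                    "evidence_label": res.reason or "",
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "matched",
            "evidence_start",
            "evidence_end",
            "evidence_label",
        ],
    ).to_csv(path, index=False)


def read_cohort(path) -> CohortResult:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    results: dict[str, PatientResult] = {}
    for row in df.itertuples(index=False):
        pid = str(row.patient_id)
        verdict = Verdict(row.matched)
        spans = []
        if row.evidence_start != "":
            spans.append(
                EvidenceSpan(
                    row.evidence_label,
                    parse_time(row.evidence_start),
                    parse_time(row.evidence_end),
                )
            )
        if pid in results:
            results[pid].evidence = results[pid].evidence + tuple(spans)
        else:
            reason = None
            if verdict is Verdict.ERROR and not spans:
                reason = row.evidence_label or None
            results[pid] = PatientResult(pid, verdict, tuple(spans), reason)
    return CohortResult(results)
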