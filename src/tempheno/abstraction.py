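"""The three interval-abstraction operators.

Clinical intervals observed in cohort definitions fall into three
categories, and each has its operator here:

* **instant-based** (:func:`abstract_instant_based`) — a maximal run of
  identical, condition-satisfying instants becomes one interval; e.g. a
  hypothermia interval abstracted from repeated low body-temperature
  measurements, or "more than 100 mL/hour of intravenous fluids".
* **bounded** (:func:`abstract_bounded`) — distinct start and end instants
  delimit the interval; e.g. hospitalization from admission/discharge.
* **moving-window** (:func:`abstract_moving_window`) — a condition must
  hold over a predefined window of time; e.g. oliguria, urinary output
  below 0.5 mL/kg/hour sustained over a 6-hour window.

All operators are deterministic and emit disjoint (instant-based,
moving-window) or non-crossing (bounded) intervals in time order.
"""

from __future__ import annotations

import numbers
import operator
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ConfigError, PreconditionError, UnitMismatchError
from .event_model import EventStream, Instant, Interval, IntervalKind

__all__ = [
    "AbstractionSpec",
    "BoundedResult",
    "Condition",
    "abstract_bounded",
    "abstract_instant_based",
    "abstract_moving_window",
    "filter_duration",
]

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "==": operator.eq,
}


@dataclass(frozen=True)
class Condition:
    """A predicate on an observation value.

    Kinds: ``threshold`` (one comparator + numeric bound), ``range``
    (inclusive numeric band with ``lower < upper``), ``categorical``
    (exact token match — the instant is used as a categorical variable
    regardless of any quantity, e.g. "receiving normal saline infusion"),
    and ``always`` (every observation qualifies).

    A condition may carry a unit. Units are opaque strings compared
    exactly: if both the condition and the observation state a unit and
    they differ, evaluation raises :class:`UnitMismatchError` rather than
    silently coercing.
    """

    kind: str = "always"
    comparator: str | None = None
    value: float | None = None
    lower: float | None = None
    upper: float | None = None
    category: str | None = None
    unit: str | None = None

    def __post_init__(self):
        if self.kind == "threshold":
            if self.comparator not in _COMPARATORS or self.value is None:
                raise ConfigError("threshold condition needs a comparator and one bound")
        elif self.kind == "range":
            if self.lower is None or self.upper is None or not self.lower < self.upper:
                raise ConfigError("range condition needs lower < upper")
        elif self.kind == "categorical":
            if self.category is None:
                raise ConfigError("categorical condition needs a category token")
        elif self.kind != "always":
            raise ConfigError(f"unknown condition kind: {self.kind!r}")

    @classmethod
    def threshold(cls, comparator: str, value: float, unit: str | None = None):
        return cls("threshold", comparator=comparator, value=value, unit=unit)

    @classmethod
    def range(cls, lower: float, upper: float, unit: str | None = None):
        return cls("range", lower=lower, upper=upper, unit=unit)

    @classmethod
    def categorical(cls, category: str):
        return cls("categorical", category=category)

    @classmethod
    def always(cls):
        return cls("always")

    def check_unit(self, unit: str | None) -> None:
        if self.unit is not None and unit is not None and self.unit != unit:
            raise UnitMismatchError(
                f"condition expects unit {self.unit!r}, observation has {unit!r}"
            )

    def satisfied(self, value, unit: str | None = None) -> bool:
        """Evaluate the predicate on one value.

        ``unit`` is checked only for numeric kinds; a categorical value has
        no unit.
        """
        if self.kind == "always":
            return True
        if self.kind == "categorical":
            return value == self.category
        self.check_unit(unit)
        if not isinstance(value, numbers.Real) or isinstance(value, bool):
            return False
        if self.kind == "threshold":
            return _COMPARATORS[self.comparator](value, self.value)
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class AbstractionSpec:
    """Parameters of one abstraction.

    ``max_gap`` (instant-based) has no universal clinical default — the
    tolerable distance between consecutive supporting instants differs per
    variable, so it is a required, explicit parameter. ``min_duration``
    filters out runs whose span is too short; when unset, only the positive
    duration demanded by the interval type itself is enforced.

    For moving windows, ``window`` is the predefined duration over which
    the condition must hold; ``window_aggregate`` selects how the
    observations inside a window are combined (see
    :func:`abstract_moving_window`); ``window_min_count`` is the minimum
    number of observations a window must contain to be evaluable — an
    under-sampled window is skipped, never silently passed.
    """

    label: str
    source_concept: str
    condition: Condition = field(default_factory=Condition.always)
    max_gap: object = None
    min_duration: object = None
    window: object = None
    window_aggregate: str = "rate"
    window_min_count: int = 1

    def __post_init__(self):
        if self.max_gap is not None and not self.max_gap > _zero(self.max_gap):
            raise ConfigError("max_gap must be > 0")
        if self.window is not None and not self.window > _zero(self.window):
            raise ConfigError("window must be > 0")
        if self.window_aggregate not in ("per_instant", "rate", "mean", "sum"):
            raise ConfigError(f"unknown window aggregate: {self.window_aggregate!r}")
        if self.window_min_count < 1:
            raise ConfigError("window_min_count must be >= 1")


def _zero(duration):
    return type(duration)(0) if isinstance(duration, pd.Timedelta) else 0


def _check_single_patient_concept(instants: Sequence[Instant], concept: str) -> None:
    concepts = {i.concept for i in instants}
    if concepts - {concept}:
        raise PreconditionError(
            f"expected instants of concept {concept!r}, got {sorted(concepts)}"
        )
    if len({i.patient_id for i in instants}) > 1:
        raise PreconditionError("instants span more than one patient")


# ---------------------------------------------------------------------------
# instant-based


def abstract_instant_based(
    instants: Sequence[Instant], spec: AbstractionSpec
) -> list[Interval]:
    """Abstract maximal runs of condition-satisfying identical instants.

    Consecutive satisfying instants belong to the same run while the gap
    between them is at most ``spec.max_gap``; each run spans
    ``[first_time, last_time]``. Runs shorter than ``spec.min_duration``
    are dropped, as are zero-span runs (a single instant, or coincident
    timestamps): an interval's duration must be strictly positive, so an
    instant-based interval needs at least two supporting instants at
    distinct times.
    """
    if spec.max_gap is None:
        raise ConfigError(f"{spec.label}: instant-based abstraction requires max_gap")
    _check_single_patient_concept(instants, spec.source_concept)
    satisfying = [
        i
        for i in instants
        if spec.condition.satisfied(
            i.transformed if i.transformed is not None else i.value, i.unit
        )
    ]
    runs: list[list[Instant]] = []
    for inst in satisfying:
        if runs and inst.time - runs[-1][-1].time <= spec.max_gap:
            runs[-1].append(inst)
        else:
            runs.append([inst])
    out = []
    for run in runs:
        span = run[-1].time - run[0].time
        if not span > _zero(span):
            continue
        if spec.min_duration is not None and span < spec.min_duration:
            continue
        out.append(
            Interval(
                patient_id=run[0].patient_id,
                concept=spec.label,
                start=run[0].time,
                end=run[-1].time,
                kind=IntervalKind.INSTANT_BASED,
                attributes={"duration": span, "count": len(run)},
                support=tuple(run),
            )
        )
    return out


# ---------------------------------------------------------------------------
# bounded


class BoundedResult(list):
    """The intervals from a bounded abstraction, plus pairing warnings.

    Behaves as a plain list of :class:`Interval`; ``warnings`` records
    every start or end instant that could not be paired, so nothing is
    ever silently dropped.
    """

    def __init__(self, intervals=(), warnings=()):
        super().__init__(intervals)
        self.warnings: list[str] = list(warnings)


def abstract_bounded(
    stream: EventStream,
    start_concept: str,
    end_concept: str,
    pairing: str = "drop",
    label: str | None = None,
    censor_time=None,
) -> BoundedResult:
    """Pair start and end instants into bounded intervals, per patient.

    Each start instant is matched greedily with the earliest strictly
    subsequent end instant not already consumed — the correct pairing for
    admission/discharge-style delimiters, including interleaved repeat
    stays. Unpaired entities are handled per ``pairing`` policy:

    * ``"drop"`` — discard, recording a warning;
    * ``"open"`` — an unmatched start is closed at ``censor_time`` (default:
      the patient's last event time);
    * ``"error"`` — raise.
    """
    if pairing not in ("drop", "open", "error"):
        raise ConfigError(f"unknown pairing policy: {pairing!r}")
    label = label or f"{start_concept}_{end_concept}"
    result = BoundedResult()
    for pid, events in stream.iter_patients():
        starts = [e.as_instant() for e in events if e.concept == start_concept]
        ends = [e.as_instant() for e in events if e.concept == end_concept]
        consumed = [False] * len(ends)
        last_time = events[-1].time if events else None
        # an end preceding every start can never pair
        for j, end in enumerate(ends):
            if not any(s.time < end.time for s in starts):
                msg = f"{pid}: {end_concept} at {end.time} has no prior {start_concept}"
                if pairing == "error":
                    raise PreconditionError(msg)
                consumed[j] = True
                result.warnings.append(msg)
        for start in starts:
            match = next(
                (
                    j
                    for j, end in enumerate(ends)
                    if not consumed[j] and end.time > start.time
                ),
                None,
            )
            if match is None:
                msg = f"{pid}: {start_concept} at {start.time} has no subsequent {end_concept}"
                if pairing == "error":
                    raise PreconditionError(msg)
                if pairing == "drop":
                    result.warnings.append(msg)
                    continue
                close = censor_time if censor_time is not None else last_time
                if close is None or not close > start.time:
                    result.warnings.append(msg + " (censoring impossible)")
                    continue
                end_inst = Instant(pid, end_concept, close)
            else:
                consumed[match] = True
                end_inst = ends[match]
            result.append(
                Interval(
                    patient_id=pid,
                    concept=label,
                    start=start.time,
                    end=end_inst.time,
                    kind=IntervalKind.BOUNDED,
                    attributes={"duration": end_inst.time - start.time},
                    support=(start, end_inst),
                )
            )
        for j, end in enumerate(ends):
            if not consumed[j]:
                result.warnings.append(
                    f"{pid}: {end_concept} at {end.time} left unpaired"
                )
    return result


# ---------------------------------------------------------------------------
# moving window


def abstract_moving_window(
    instants: Sequence[Instant],
    spec: AbstractionSpec,
    external: float | None = None,
) -> list[Interval]:
    """Detect spans where a condition holds over a predefined window.

    A window of length ``spec.window`` is anchored at every observation
    time ``t`` and covers ``[t, t + window]`` (closed). The observations
    inside it are combined per ``spec.window_aggregate``:

    * ``rate`` — sum of (external-normalised) values divided by the window
      length in hours, e.g. urine output in mL/kg/h against a 70 kg body
      weight; requires ``external``;
    * ``per_instant`` — the condition must hold at every observation in the
      window individually;
    * ``mean`` / ``sum`` — the condition applies to the mean or sum.

    When ``external`` is given, each value is divided by it before
    aggregation. Windows containing fewer than ``spec.window_min_count``
    observations are skipped as unevaluable (a half-empty window must not
    masquerade as a low rate); windows with no observations are always
    skipped. Overlapping or abutting satisfying windows are merged, and
    each maximal union is emitted as one interval.
    """
    if spec.window is None:
        raise ConfigError(f"{spec.label}: moving-window abstraction requires window")
    if spec.window_aggregate == "rate" and external is None:
        raise ConfigError(
            f"{spec.label}: rate aggregate requires an external scalar (e.g. body weight)"
        )
    if external is not None and not external > 0:
        raise ConfigError(f"{spec.label}: external scalar must be > 0")
    _check_single_patient_concept(instants, spec.source_concept)

    satisfied_windows = []
    for anchor in instants:
        t0, t1 = anchor.time, anchor.time + spec.window
        ok = _window_satisfied(instants, t0, t1, spec, external)
        if ok:
            satisfied_windows.append((t0, t1))

    out = []
    for start, end in _merge_spans(satisfied_windows):
        support = tuple(i for i in instants if start <= i.time <= end)
        out.append(
            Interval(
                patient_id=instants[0].patient_id,
                concept=spec.label,
                start=start,
                end=end,
                kind=IntervalKind.MOVING_WINDOW,
                attributes={"duration": end - start},
                support=support,
            )
        )
    return out


def _window_satisfied(instants, t0, t1, spec: AbstractionSpec, external) -> bool:
    values = []
    for i in instants:
        if t0 <= i.time <= t1:
            v = i.value
            if not isinstance(v, numbers.Real) or isinstance(v, bool):
                return False
            spec.condition.check_unit(None if external is not None else i.unit)
            values.append(v / external if external is not None else v)
    if len(values) < max(spec.window_min_count, 1):
        return False
    cond = spec.condition
    if spec.window_aggregate == "per_instant":
        return all(cond.satisfied(v) for v in values)
    if spec.window_aggregate == "mean":
        return cond.satisfied(sum(values) / len(values))
    if spec.window_aggregate == "sum":
        return cond.satisfied(sum(values))
    return cond.satisfied(sum(values) / _hours(spec.window))


def _hours(duration) -> float:
    """Window length in hours; unit-free numeric timelines count 1 per hour."""
    if isinstance(duration, pd.Timedelta):
        return duration / pd.Timedelta(hours=1)
    return float(duration)


def _merge_spans(spans):
    """Union of closed spans; overlapping or abutting spans merge."""
    merged = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# arithmetic filters


def filter_duration(
    intervals: Sequence[Interval], comparator: str, bound
) -> list[Interval]:
    """Keep intervals whose duration satisfies ``comparator bound``.

    Comparators are the usual ``< <= > >= ==`` with their exact boundary
    semantics — "at least 48 hours" (``>= 48h``) keeps an interval of
    exactly 48 hours. Order is preserved.
    """
    if comparator not in _COMPARATORS:
        raise ConfigError(f"unknown comparator: {comparator!r}")
    op = _COMPARATORS[comparator]
    return [i for i in intervals if op(i.duration, bound)]
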