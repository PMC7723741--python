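"""Allen's interval algebra, plus the point calculi needed for instants.

Between two well-formed intervals (``end > start``) exactly one of Allen's
13 qualitative relations holds: ``before``, ``meets``, ``overlaps``,
``starts``, ``during``, ``finishes``, ``equal`` and the six converses
(``after``, ``met_by``, ``overlapped_by``, ``started_by``, ``contains``,
``finished_by``). ``meets`` means the first interval's end coincides with
the second's start; ``overlaps`` requires a strictly interior crossing.

Instants are never coerced to degenerate intervals. A point relates to an
interval through a 5-label reduction (``before, starts, during, finishes,
after`` — a zero-duration entity cannot "meet"), and two points through the
trichotomy (``before, equal, after``).

:func:`holds` evaluates a constrained relation — a label set optionally
tightened by a gap bound, which is how criteria such as "within 48 hours of
admission" are expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import ConfigError, PreconditionError
from .event_model import Instant, Interval

__all__ = [
    "RelationLabel",
    "RelationConstraint",
    "classify",
    "classify_point",
    "classify_points",
    "converse",
    "holds",
    "relate",
]


class RelationLabel(str, Enum):
    BEFORE = "before"
    MEETS = "meets"
    OVERLAPS = "overlaps"
    STARTS = "starts"
    DURING = "during"
    FINISHES = "finishes"
    EQUAL = "equal"
    AFTER = "after"
    MET_BY = "met_by"
    OVERLAPPED_BY = "overlapped_by"
    STARTED_BY = "started_by"
    CONTAINS = "contains"
    FINISHED_BY = "finished_by"


_CONVERSE = {
    RelationLabel.BEFORE: RelationLabel.AFTER,
    RelationLabel.MEETS: RelationLabel.MET_BY,
    RelationLabel.OVERLAPS: RelationLabel.OVERLAPPED_BY,
    RelationLabel.STARTS: RelationLabel.STARTED_BY,
    RelationLabel.DURING: RelationLabel.CONTAINS,
    RelationLabel.FINISHES: RelationLabel.FINISHED_BY,
    RelationLabel.EQUAL: RelationLabel.EQUAL,
}
_CONVERSE.update({v: k for k, v in list(_CONVERSE.items())})

#: Labels in which the two entities are separated by a gap.
GAP_LABELS = frozenset({RelationLabel.BEFORE, RelationLabel.AFTER})


def converse(label: RelationLabel) -> RelationLabel:
    """The relation seen from the second entity's point of view."""
    return _CONVERSE[RelationLabel(label)]


def _check(interval) -> None:
    if not interval.end > interval.start:
        raise PreconditionError(f"malformed interval [{interval.start}, {interval.end}]")


def classify(a, b) -> RelationLabel:
    """The unique Allen relation holding between intervals ``a`` and ``b``.

    Accepts any objects with comparable ``start``/``end`` attributes and
    ``end > start``.
    """
    _check(a)
    _check(b)
    if a.end < b.start:
        return RelationLabel.BEFORE
    if b.end < a.start:
        return RelationLabel.AFTER
    if a.end == b.start:
        return RelationLabel.MEETS
    if b.end == a.start:
        return RelationLabel.MET_BY
    # the interiors now intersect
    if a.start == b.start:
        if a.end == b.end:
            return RelationLabel.EQUAL
        return RelationLabel.STARTS if a.end < b.end else RelationLabel.STARTED_BY
    if a.end == b.end:
        return RelationLabel.FINISHES if a.start > b.start else RelationLabel.FINISHED_BY
    if a.start < b.start:
        return RelationLabel.CONTAINS if a.end > b.end else RelationLabel.OVERLAPS
    return RelationLabel.DURING if a.end < b.end else RelationLabel.OVERLAPPED_BY


def classify_point(p, i) -> RelationLabel:
    """Relate an instant to an interval (inclusive bounds).

    Returns one of ``before``, ``starts``, ``during``, ``finishes``,
    ``after``: the five relations a timepoint can bear to a closed interval.
    """
    _check(i)
    t = p.time
    if t < i.start:
        return RelationLabel.BEFORE
    if t == i.start:
        return RelationLabel.STARTS
    if t < i.end:
        return RelationLabel.DURING
    if t == i.end:
        return RelationLabel.FINISHES
    return RelationLabel.AFTER


def classify_points(p, q) -> RelationLabel:
    """Trichotomy between two instants: ``before``, ``equal`` or ``after``."""
    if p.time < q.time:
        return RelationLabel.BEFORE
    if p.time == q.time:
        return RelationLabel.EQUAL
    return RelationLabel.AFTER


def relate(a, b) -> RelationLabel:
    """Classify any pair of temporal entities (instant or interval)."""
    a_pt, b_pt = _is_point(a), _is_point(b)
    if a_pt and b_pt:
        return classify_points(a, b)
    if a_pt:
        return classify_point(a, b)
    if b_pt:
        return converse(classify_point(b, a))
    return classify(a, b)


def _is_point(entity) -> bool:
    return isinstance(entity, Instant) or (
        not hasattr(entity, "start") and hasattr(entity, "time")
    )


def _bounds(entity):
    if _is_point(entity):
        return entity.time, entity.time
    return entity.start, entity.end


@dataclass(frozen=True)
class RelationConstraint:
    """A set of admissible relation labels, optionally gap-bounded.

    ``gap_min``/``gap_max`` bound the separation between the entities and
    are only meaningful for ``before``/``after`` — the labels with a gap.
    For ``before`` the gap is ``b.start − a.end``; for ``after`` it is
    ``a.start − b.end``.
    """

    labels: frozenset = field(default_factory=frozenset)
    gap_min: object = None
    gap_max: object = None

    def __post_init__(self):
        labels = frozenset(RelationLabel(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise ConfigError("relation constraint needs at least one label")
        if (self.gap_min is not None or self.gap_max is not None) and not labels <= GAP_LABELS:
            bad = sorted(l.value for l in labels - GAP_LABELS)
            raise ConfigError(
                f"gap bounds are only valid for before/after, not {bad}"
            )


def holds(a, b, constraint: RelationConstraint) -> bool:
    """True iff the relation between ``a`` and ``b`` is in the constraint's
    label set and any gap bounds are satisfied."""
    label = relate(a, b)
    if label not in constraint.labels:
        return False
    if constraint.gap_min is None and constraint.gap_max is None:
        return True
    a_start, a_end = _bounds(a)
    b_start, b_end = _bounds(b)
    gap = b_start - a_end if label is RelationLabel.BEFORE else a_start - b_end
    if constraint.gap_min is not None and gap < constraint.gap_min:
        return False
    if constraint.gap_max is not None and gap > constraint.gap_max:
        return False
    return True
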