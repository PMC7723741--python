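"""Within-interval calculations and external-variable conditions.

Two families of computation decorate abstracted intervals:

* **within-interval aggregates** — combining the instants that fall inside
  an interval, e.g. counting the chest x-rays performed during an ICU stay,
  or summing drug doses into a ``total_dose`` attribute. A registered
  formula mechanism covers derived quantities; pulse pressure variation
  (:func:`ppv`) is the built-in example.

* **external-variable conditions** — a per-patient scalar (typically body
  weight) enters the criterion either *before* abstraction, transforming
  each instant (urine output mL/h → mL/kg/h), or *after* abstraction,
  transforming a derived interval attribute (total prednisone dose →
  mg/kg). A missing external variable is an explicit evaluation error for
  that patient, never a silent pass or fail.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .abstraction import Condition
from .errors import ConfigError, DomainError, PatientEvaluationError, VocabularyError
from .event_model import EventStream, Instant, Interval, PatientAttributes, select

__all__ = [
    "AggregateSpec",
    "ExternalCondition",
    "aggregate",
    "apply_post",
    "apply_pre",
    "ppv",
    "register_formula",
]


def ppv(pp_max: float, pp_min: float) -> float:
    """Pulse pressure variation, as a percentage.

    PPV(%) = 100 × 2 × (PPmax − PPmin) / (PPmax + PPmin),
    where PPmax and PPmin are the extreme pulse pressures over the
    caller's chosen span of instants. Scale-invariant by construction.
    """
    if pp_max < pp_min:
        raise DomainError(f"pp_max ({pp_max}) < pp_min ({pp_min})")
    if not pp_max + pp_min > 0:
        raise DomainError("pp_max + pp_min must be positive")
    return 100.0 * 2.0 * (pp_max - pp_min) / (pp_max + pp_min)


def _ppv_over(values: Sequence[float]) -> float:
    return ppv(max(values), min(values))


#: name → pure function of the numeric values inside the interval
_FORMULAS: dict[str, Callable[[Sequence[float]], float]] = {"ppv": _ppv_over}


def register_formula(name: str, fn: Callable[[Sequence[float]], float]) -> None:
    """Register a named formula usable with ``op="formula"``."""
    _FORMULAS[name] = fn


@dataclass(frozen=True)
class AggregateSpec:
    """How to aggregate one concept's instants inside an interval.

    ``op`` is one of ``count, sum, mean, min, max, formula``;
    ``formula_name`` selects a registered formula when ``op="formula"``.
    The result is stored in the interval's attributes under ``name``
    (default: ``"<op>_<target_concept>"``).
    """

    op: str
    target_concept: str
    formula_name: str | None = None
    name: str | None = None

    def __post_init__(self):
        if self.op not in ("count", "sum", "mean", "min", "max", "formula"):
            raise ConfigError(f"unknown aggregate op: {self.op!r}")
        if self.op == "formula":
            if self.formula_name not in _FORMULAS:
                raise VocabularyError(
                    f"formula {self.formula_name!r} is not registered"
                )
        elif self.formula_name is not None:
            raise ConfigError("formula_name is only valid with op='formula'")

    @property
    def attribute_name(self) -> str:
        if self.name:
            return self.name
        if self.op == "formula":
            return f"{self.formula_name}_{self.target_concept}"
        return f"{self.op}_{self.target_concept}"


def aggregate(interval: Interval, stream: EventStream, spec: AggregateSpec):
    """Aggregate the target concept's instants inside the interval.

    Bounds are closed on both ends, consistent with the rest of the
    package. ``count`` of an empty set is 0; ``sum`` of an empty set is 0;
    ``mean``/``min``/``max``/formulas over an empty set yield ``None``
    ("absent") — 0 is a valid measurement and must not be fabricated. The
    result is also written into ``interval.attributes``.
    """
    inside = [
        i
        for i in select(stream, spec.target_concept, interval.patient_id)
        if interval.start <= i.time <= interval.end
    ]
    if spec.op == "count":
        result = len(inside)
    else:
        values = [
            i.value
            for i in inside
            if isinstance(i.value, numbers.Real) and not isinstance(i.value, bool)
        ]
        if spec.op == "sum":
            result = float(sum(values))
        elif not values:
            result = None
        elif spec.op == "mean":
            result = float(sum(values) / len(values))
        elif spec.op == "min":
            result = float(min(values))
        elif spec.op == "max":
            result = float(max(values))
        else:
            result = float(_FORMULAS[spec.formula_name](values))
    if result is not None:
        interval.attributes[spec.attribute_name] = result
    return result


@dataclass(frozen=True)
class ExternalCondition:
    """A criterion involving a per-patient scalar outside the event stream.

    ``stage="pre"`` transforms every instant's value before abstraction
    (e.g. divide urine output by body weight, then test < 0.5 mL/kg/h);
    ``stage="post"`` transforms one derived attribute of an already
    abstracted interval (e.g. divide ``total_dose`` by body weight, then
    test < 10 mg/kg). ``transform`` names how the variable enters; only
    division is currently meaningful, matching the weight-normalised
    criteria seen in practice.
    """

    stage: str
    variable: str
    condition: Condition
    transform: str = "divide_value"
    attribute: str | None = None  # post stage: which interval attribute

    def __post_init__(self):
        if self.stage not in ("pre", "post"):
            raise ConfigError(f"stage must be 'pre' or 'post', got {self.stage!r}")
        if self.transform not in ("divide_value", "divide_aggregate"):
            raise ConfigError(f"unknown transform: {self.transform!r}")
        if self.stage == "post" and self.attribute is None:
            raise ConfigError("post-stage condition needs the interval attribute name")


def _external_scalar(cond: ExternalCondition, attrs: PatientAttributes) -> float:
    value = attrs.get(cond.variable)
    if value is None:
        raise PatientEvaluationError(
            f"patient {attrs.patient_id}: external variable {cond.variable!r} missing"
        )
    if not isinstance(value, numbers.Real) or not value > 0:
        raise PatientEvaluationError(
            f"patient {attrs.patient_id}: external variable {cond.variable!r} "
            f"is not a positive number ({value!r})"
        )
    return float(value)


def apply_pre(
    instants: Sequence[Instant],
    cond: ExternalCondition,
    attrs: PatientAttributes,
) -> list[Instant]:
    """Filter instants by a pre-abstraction external condition.

    Each instant's value is divided by the external variable, the condition
    is evaluated on the transformed value, and satisfying instants pass
    through with the transformed value recorded alongside the original.
    """
    if cond.stage != "pre":
        raise ConfigError("apply_pre requires a pre-stage condition")
    scalar = _external_scalar(cond, attrs)
    out = []
    for inst in instants:
        if not isinstance(inst.value, numbers.Real) or isinstance(inst.value, bool):
            continue
        transformed = inst.value / scalar
        if cond.condition.satisfied(transformed):
            out.append(replace(inst, transformed=transformed))
    return out


def apply_post(
    interval: Interval,
    cond: ExternalCondition,
    attrs: PatientAttributes,
) -> bool:
    """Evaluate a post-abstraction external condition on one interval.

    The referenced interval attribute is divided by the external variable
    and the condition is evaluated on the quotient; the caller keeps the
    interval iff the result is true. The transformed value is recorded in
    the interval's attributes for traceability.
    """
    if cond.stage != "post":
        raise ConfigError("apply_post requires a post-stage condition")
    scalar = _external_scalar(cond, attrs)
    if cond.attribute not in interval.attributes:
        raise PatientEvaluationError(
            f"patient {interval.patient_id}: interval attribute "
            f"{cond.attribute!r} missing (have {sorted(interval.attributes)})"
        )
    raw = interval.attributes[cond.attribute]
    if not isinstance(raw, numbers.Real):
        raise PatientEvaluationError(
            f"patient {interval.patient_id}: attribute {cond.attribute!r} "
            f"is not numeric ({raw!r})"
        )
    transformed = raw / scalar
    interval.attributes[f"{cond.attribute}_per_{cond.variable}"] = transformed
    return cond.condition.satisfied(transformed)
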