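"""Phenotype patterns: composition, declarative parsing, and evaluation.

A phenotype is an abstract-syntax tree whose leaves are temporal entities
(instants or abstracted intervals) and whose inner nodes compose them:

* a **basic pattern** relates two entities (or sub-patterns) through a
  temporal relation constraint — entity–relation–entity;
* **Boolean nodes** combine patient-level verdicts with AND, OR, XOR, NOT;
* **attribute filters** add non-temporal patient conditions (age, sex …);
* a **nested query** evaluates an outcome phenotype only within the cohort
  matched by an exposure phenotype — SELECT (outcome) FROM (exposure).

Matching is existential: a basic pattern matches a patient iff *some* pair
of materialized entities satisfies the relation, and every satisfying pair
is retained as evidence. NOT negates the patient-level verdict; it does
not complement intervals on the timeline. Evaluation is per-patient
independent and fully deterministic.

Patterns can be built directly from the dataclasses here or parsed from a
declarative YAML/JSON document (see :func:`parse_pattern`).
"""

from __future__ import annotations

import dataclasses
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .abstraction import (
    AbstractionSpec,
    Condition,
    abstract_bounded,
    abstract_instant_based,
    abstract_moving_window,
    filter_duration,
)
from .calculations import AggregateSpec, ExternalCondition, aggregate, apply_post, apply_pre
from .errors import (
    ConfigError,
    PatientEvaluationError,
    SchemaError,
    UnitMismatchError,
    VocabularyError,
)
from .event_model import (
    CohortResult,
    EventStream,
    EvidenceSpan,
    Instant,
    Interval,
    PatientAttributes,
    PatientResult,
    Verdict,
    parse_duration,
    select,
)
from .relations import RelationConstraint, RelationLabel, holds

__all__ = [
    "AttributeFilterNode",
    "BasicNode",
    "BooleanNode",
    "EntityNode",
    "EntitySpec",
    "NestedNode",
    "PhenotypePattern",
    "evaluate",
    "evaluate_nested",
    "filter_attributes",
    "instant_leaves",
    "iter_nodes",
    "parse_pattern",
    "serialize_pattern",
    "validate_pattern",
]


# ---------------------------------------------------------------------------
# entity specifications


@dataclass(frozen=True)
class EntitySpec:
    """Declaration of one temporal entity.

    ``type`` selects the materialization: ``instant`` (condition-filtered
    raw instants) or one of the three interval abstractions
    (``instant_based``, ``bounded``, ``moving_window``). The remaining
    fields mirror the abstraction parameters; ``duration_op`` /
    ``duration_bound`` express arithmetic filters such as "hospitalization
    longer than 7 days"; ``aggregates`` compute within-interval attributes
    (counts, total doses, registered formulas); ``pre`` / ``post`` attach
    external-variable conditions before or after abstraction.
    """

    name: str
    type: str
    concept: str | None = None
    condition: Condition = field(default_factory=Condition.always)
    max_gap: object = None
    min_duration: object = None
    window: object = None
    window_aggregate: str = "rate"
    window_min_count: int = 1
    external: str | None = None
    start_concept: str | None = None
    end_concept: str | None = None
    pairing: str = "drop"
    duration_op: str | None = None
    duration_bound: object = None
    pre: ExternalCondition | None = None
    post: ExternalCondition | None = None
    aggregates: tuple[AggregateSpec, ...] = ()

    def __post_init__(self):
        if self.type not in ("instant", "instant_based", "bounded", "moving_window"):
            raise VocabularyError(f"unknown entity type: {self.type!r}")
        if self.type == "bounded":
            if not (self.start_concept and self.end_concept):
                raise ConfigError(f"{self.name}: bounded entity needs start/end concepts")
        elif self.concept is None:
            raise ConfigError(f"{self.name}: entity needs a source concept")
        if self.type == "instant_based" and self.max_gap is None:
            raise ConfigError(f"{self.name}: instant-based entity needs max_gap")
        if self.type == "moving_window" and self.window is None:
            raise ConfigError(f"{self.name}: moving-window entity needs window")
        if (self.duration_op is None) != (self.duration_bound is None):
            raise ConfigError(f"{self.name}: duration filter needs op and bound")

    # -- materialization ---------------------------------------------------

    def materialize(
        self, substream: EventStream, patient_id: str, attrs: PatientAttributes
    ) -> list:
        """Instantiate this entity from one patient's events."""
        if self.type == "bounded":
            entities = list(
                abstract_bounded(
                    substream,
                    self.start_concept,
                    self.end_concept,
                    pairing=self.pairing,
                    label=self.name,
                )
            )
        else:
            instants = select(substream, self.concept, patient_id)
            if self.pre is not None:
                instants = apply_pre(instants, self.pre, attrs)
            if self.type == "instant":
                # matched instants take the entity's name as their label,
                # like abstracted intervals do
                entities = [
                    dataclasses.replace(i, concept=self.name)
                    for i in instants
                    if self.condition.satisfied(
                        i.transformed if i.transformed is not None else i.value,
                        i.unit,
                    )
                ]
            elif self.type == "instant_based":
                spec = AbstractionSpec(
                    label=self.name,
                    source_concept=self.concept,
                    condition=self.condition,
                    max_gap=self.max_gap,
                    min_duration=self.min_duration,
                )
                entities = abstract_instant_based(instants, spec)
            else:  # moving_window
                scalar = None
                if self.external is not None:
                    value = attrs.get(self.external)
                    if value is None or not isinstance(value, numbers.Real):
                        raise PatientEvaluationError(
                            f"patient {patient_id}: external variable "
                            f"{self.external!r} missing"
                        )
                    scalar = float(value)
                spec = AbstractionSpec(
                    label=self.name,
                    source_concept=self.concept,
                    condition=self.condition,
                    window=self.window,
                    window_aggregate=self.window_aggregate,
                    window_min_count=self.window_min_count,
                )
                entities = [] if not instants else abstract_moving_window(
                    instants, spec, scalar
                )
        # decorate intervals, then apply post conditions and duration filters
        kept = []
        for ent in entities:
            if isinstance(ent, Interval):
                for agg in self.aggregates:
                    aggregate(ent, substream, agg)
                if self.post is not None and not apply_post(ent, self.post, attrs):
                    continue
            kept.append(ent)
        if self.duration_op is not None:
            intervals = [e for e in kept if isinstance(e, Interval)]
            kept = filter_duration(intervals, self.duration_op, self.duration_bound)
        return kept


# ---------------------------------------------------------------------------
# pattern nodes


@dataclass(frozen=True)
class EntityNode:
    spec: EntitySpec

    @property
    def label(self) -> str:
        return self.spec.name


@dataclass(frozen=True)
class BasicNode:
    """Entity–relation–entity (or pattern–relation–pattern)."""

    left: "PhenotypePattern"
    constraint: RelationConstraint
    right: "PhenotypePattern"
    label: str = "basic"


@dataclass(frozen=True)
class BooleanNode:
    op: str
    children: tuple
    label: str = "boolean"

    def __post_init__(self):
        if self.op not in ("and", "or", "xor", "not"):
            raise VocabularyError(f"unknown Boolean operator: {self.op!r}")
        n = len(self.children)
        if self.op == "not" and n != 1:
            raise ConfigError("NOT takes exactly one child")
        if self.op == "xor" and n != 2:
            raise ConfigError("XOR takes exactly two children")
        if self.op in ("and", "or") and n < 2:
            raise ConfigError(f"{self.op.upper()} takes at least two children")


@dataclass(frozen=True)
class AttributeFilterNode:
    """Non-temporal patient attribute condition AND a child pattern."""

    attribute: str
    condition: Condition
    child: "PhenotypePattern"
    label: str = "where"


@dataclass(frozen=True)
class NestedNode:
    """SELECT (outcome) FROM (exposure): the outcome phenotype is evaluated
    only on the cohort matched by the exposure phenotype."""

    outcome: "PhenotypePattern"
    exposure: "PhenotypePattern"
    label: str = "nested"


PhenotypePattern = Union[EntityNode, BasicNode, BooleanNode, AttributeFilterNode, NestedNode]


def iter_nodes(pattern: PhenotypePattern):
    """Depth-first iteration over all nodes of a pattern tree."""
    yield pattern
    if isinstance(pattern, BasicNode):
        yield from iter_nodes(pattern.left)
        yield from iter_nodes(pattern.right)
    elif isinstance(pattern, BooleanNode):
        for child in pattern.children:
            yield from iter_nodes(child)
    elif isinstance(pattern, AttributeFilterNode):
        yield from iter_nodes(pattern.child)
    elif isinstance(pattern, NestedNode):
        yield from iter_nodes(pattern.outcome)
        yield from iter_nodes(pattern.exposure)


def instant_leaves(pattern: PhenotypePattern) -> list[EntityNode]:
    """All entity leaves of type ``instant`` (in depth-first order)."""
    return [
        n
        for n in iter_nodes(pattern)
        if isinstance(n, EntityNode) and n.spec.type == "instant"
    ]


def validate_pattern(pattern: PhenotypePattern) -> None:
    """Structural validation; raises :class:`ConfigError` on violations.

    Node constructors enforce arity; this re-walks the tree so patterns
    assembled by other means get the same checks. All node classes are
    immutable, so a pattern can never contain a cycle; sharing a subtree
    between branches is allowed (evaluation is pure).
    """

    def walk(node):
        if isinstance(node, BasicNode):
            walk(node.left)
            walk(node.right)
        elif isinstance(node, BooleanNode):
            BooleanNode(node.op, node.children)  # re-check arity
            for child in node.children:
                walk(child)
        elif isinstance(node, AttributeFilterNode):
            walk(node.child)
        elif isinstance(node, NestedNode):
            walk(node.outcome)
            walk(node.exposure)
        elif not isinstance(node, EntityNode):
            raise ConfigError(f"unknown pattern node: {type(node).__name__}")

    walk(pattern)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(pattern: PhenotypePattern, stream: EventStream) -> CohortResult:
    """Evaluate a phenotype over a stream, one verdict per patient.

    Data problems local to a patient (a missing external variable, a unit
    mismatch in their records) yield an ``error`` verdict for that patient;
    they never abort the cohort run. Structural problems in the pattern
    itself raise before any patient is evaluated.
    """
    validate_pattern(pattern)
    if isinstance(pattern, NestedNode):
        return evaluate_nested(pattern.outcome, pattern.exposure, stream)

    results: dict[str, PatientResult] = {}
    for pid, substream in _per_patient(stream):
        attrs = stream.attributes_for(pid)
        try:
            matched, entities = _eval_node(pattern, substream, pid, attrs)
        except (PatientEvaluationError, UnitMismatchError) as exc:
            results[pid] = PatientResult(pid, Verdict.ERROR, (), str(exc))
            continue
        verdict = Verdict.MATCHED if matched else Verdict.NOT_MATCHED
        results[pid] = PatientResult(pid, verdict, _spans(entities))
    return CohortResult(results)


def evaluate_nested(
    outcome: PhenotypePattern, exposure: PhenotypePattern, stream: EventStream
) -> CohortResult:
    """SELECT (outcome) FROM (exposure).

    The exposure phenotype is evaluated on the full stream; the outcome
    phenotype only on the sub-stream of exposure-matched patients. A
    patient matches iff they match both; evidence from both layers is
    retained. The matched set is therefore always a subset of the
    exposure's matched set.
    """
    exposure_result = evaluate(exposure, stream)
    cohort = sorted(exposure_result.matched)
    outcome_result = evaluate(outcome, stream.restrict(cohort))

    results: dict[str, PatientResult] = {}
    for pid, exp_res in exposure_result.results.items():
        if exp_res.verdict is Verdict.ERROR:
            results[pid] = exp_res
        elif exp_res.verdict is Verdict.NOT_MATCHED:
            results[pid] = PatientResult(
                pid, Verdict.NOT_MATCHED, (), "exposure not matched"
            )
        else:
            out_res = outcome_result[pid]
            evidence = exp_res.evidence + out_res.evidence
            if out_res.verdict is Verdict.MATCHED:
                results[pid] = PatientResult(pid, Verdict.MATCHED, evidence)
            else:
                results[pid] = PatientResult(
                    pid, out_res.verdict, out_res.evidence, out_res.reason
                )
    return CohortResult(results)


def filter_attributes(
    cohort: CohortResult,
    attributes: Mapping[str, PatientAttributes],
    attribute: str,
    condition: Condition,
) -> CohortResult:
    """Intersect a cohort's matched set with an attribute condition.

    A matched patient lacking the attribute gets an ``error`` verdict —
    never a silent exclusion. An attribute name unknown to every patient is
    a validation error.
    """
    if not any(attribute in pa.attributes for pa in attributes.values()):
        raise VocabularyError(f"attribute {attribute!r} unknown to every patient")
    results: dict[str, PatientResult] = {}
    for pid, res in cohort.results.items():
        if res.verdict is not Verdict.MATCHED:
            results[pid] = res
            continue
        pa = attributes.get(pid)
        value = pa.get(attribute) if pa is not None else None
        if value is None:
            results[pid] = PatientResult(
                pid, Verdict.ERROR, (), f"attribute {attribute!r} missing"
            )
        elif condition.satisfied(value):
            results[pid] = res
        else:
            results[pid] = PatientResult(pid, Verdict.NOT_MATCHED, ())
    return CohortResult(results)


def _per_patient(stream: EventStream):
    """Split a stream into single-patient substreams (one pass)."""
    grouped: dict[str, list] = {pid: [] for pid in stream.patient_ids}
    for event in stream.events:
        grouped[event.patient_id].append(event)
    for pid, events in grouped.items():
        sub = EventStream.__new__(EventStream)
        sub.events = events
        sub.attributes = (
            {pid: stream.attributes[pid]} if pid in stream.attributes else {}
        )
        sub.validation = []
        yield pid, sub


def _eval_node(node, substream, pid, attrs):
    if isinstance(node, EntityNode):
        entities = node.spec.materialize(substream, pid, attrs)
        return bool(entities), entities
    if isinstance(node, BasicNode):
        l_matched, l_ents = _eval_node(node.left, substream, pid, attrs)
        r_matched, r_ents = _eval_node(node.right, substream, pid, attrs)
        if not (l_matched and r_matched):
            return False, []
        witnesses, seen = [], set()
        for x in l_ents:
            for y in r_ents:
                if holds(x, y, node.constraint):
                    for ent in (x, y):
                        if id(ent) not in seen:
                            seen.add(id(ent))
                            witnesses.append(ent)
        return bool(witnesses), witnesses
    if isinstance(node, BooleanNode):
        child_results = [
            _eval_node(child, substream, pid, attrs) for child in node.children
        ]
        verdicts = [m for m, _ in child_results]
        if node.op == "and":
            matched = all(verdicts)
        elif node.op == "or":
            matched = any(verdicts)
        elif node.op == "xor":
            matched = verdicts[0] != verdicts[1]
        else:
            matched = not verdicts[0]
        evidence = []
        if matched and node.op != "not":
            for m, ents in child_results:
                if m:
                    evidence.extend(ents)
        return matched, evidence
    if isinstance(node, AttributeFilterNode):
        value = attrs.get(node.attribute)
        if value is None:
            raise PatientEvaluationError(
                f"patient {pid}: attribute {node.attribute!r} missing"
            )
        if not node.condition.satisfied(value):
            return False, []
        return _eval_node(node.child, substream, pid, attrs)
    if isinstance(node, NestedNode):
        raise ConfigError("nested queries are only supported at the top level")
    raise ConfigError(f"unknown pattern node: {type(node).__name__}")


def _spans(entities) -> tuple[EvidenceSpan, ...]:
    spans = []
    for ent in entities:
        if isinstance(ent, Instant):
            spans.append(EvidenceSpan(ent.concept, ent.time, ent.time))
        else:
            spans.append(EvidenceSpan(ent.concept, ent.start, ent.end))
    return tuple(spans)


# ---------------------------------------------------------------------------
# declarative documents


_RELATION_NAMES = {l.value for l in RelationLabel}


def parse_pattern(doc) -> PhenotypePattern:
    """Parse a declarative phenotype document into a pattern tree.

    ``doc`` may be a mapping, a YAML string, or a path to a YAML/JSON
    file. Layout::

        phenotype: <name>
        entities:
          <name>: {type: instant|instant_based|bounded|moving_window, ...}
        pattern: <node>
        nested:            # optional
          exposure: <node>

    Pattern nodes are entity names (strings), relation nodes
    ``{relation: {left, rel, right, gap_min, gap_max}}``, Boolean nodes
    ``{and|or|xor: [...]}'' / ``{not: ...}``, or attribute filters
    ``{where: {attribute, condition}, pattern: ...}``. Schema violations
    raise :class:`SchemaError` with the path to the offending node;
    unknown relation or operator names raise :class:`VocabularyError`.
    """
    doc = _load_doc(doc)
    if not isinstance(doc, Mapping):
        raise SchemaError("$", "document must be a mapping")
    if "pattern" not in doc:
        raise SchemaError("$", "missing required key 'pattern'")
    entities = {}
    raw_entities = doc.get("entities", {})
    if not isinstance(raw_entities, Mapping):
        raise SchemaError("entities", "must be a mapping of name -> spec")
    for name, raw in raw_entities.items():
        entities[name] = _parse_entity(name, raw, f"entities.{name}")
    pattern = _parse_node(doc["pattern"], entities, "pattern")
    nested = doc.get("nested")
    if nested is not None:
        if not isinstance(nested, Mapping) or "exposure" not in nested:
            raise SchemaError("nested", "must be a mapping with key 'exposure'")
        exposure = _parse_node(nested["exposure"], entities, "nested.exposure")
        pattern = NestedNode(outcome=pattern, exposure=exposure)
    validate_pattern(pattern)
    return pattern


def _load_doc(doc):
    if isinstance(doc, Mapping):
        return doc
    if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc and doc.endswith((".yaml", ".yml", ".json"))):
        with open(doc) as fh:
            return yaml.safe_load(fh)
    if isinstance(doc, str):
        return yaml.safe_load(doc)
    raise SchemaError("$", f"cannot interpret document of type {type(doc).__name__}")


def _parse_condition(raw, path) -> Condition:
    if raw is None or raw == "always":
        return Condition.always()
    if not isinstance(raw, Mapping):
        raise SchemaError(path, "condition must be a mapping or 'always'")
    unit = raw.get("unit")
    if "category" in raw:
        return Condition.categorical(raw["category"])
    op = raw.get("op")
    if op == "between":
        try:
            return Condition.range(float(raw["lower"]), float(raw["upper"]), unit)
        except KeyError as exc:
            raise SchemaError(path, f"between condition missing {exc}") from None
    if op is None or "value" not in raw:
        raise SchemaError(path, "condition needs 'op' and 'value' (or 'category')")
    value = raw["value"]
    if isinstance(value, str):
        if op != "==":
            raise SchemaError(path, "string values only support op '=='")
        return Condition.categorical(value)
    try:
        return Condition.threshold(op, float(value), unit)
    except ConfigError as exc:
        raise SchemaError(path, str(exc)) from None


def _parse_external(raw, stage, path) -> ExternalCondition:
    if not isinstance(raw, Mapping) or "variable" not in raw:
        raise SchemaError(path, "external condition needs 'variable'")
    return ExternalCondition(
        stage=stage,
        variable=raw["variable"],
        condition=_parse_condition(raw.get("condition"), f"{path}.condition"),
        transform=raw.get("transform", "divide_value" if stage == "pre" else "divide_aggregate"),
        attribute=raw.get("attribute"),
    )


_ENTITY_KEYS = {
    "type", "concept", "condition", "max_gap", "min_duration", "window",
    "aggregate", "min_count", "external", "start_concept", "end_concept",
    "pairing", "duration", "pre", "post", "aggregates",
}


def _parse_entity(name, raw, path) -> EntitySpec:
    if not isinstance(raw, Mapping):
        raise SchemaError(path, "entity spec must be a mapping")
    unknown = set(raw) - _ENTITY_KEYS
    if unknown:
        raise SchemaError(path, f"unknown key(s): {sorted(unknown)}")
    if "type" not in raw:
        raise SchemaError(path, "entity needs a 'type'")
    duration_op = duration_bound = None
    if "duration" in raw:
        d = raw["duration"]
        if not isinstance(d, Mapping) or "op" not in d or "value" not in d:
            raise SchemaError(f"{path}.duration", "needs 'op' and 'value'")
        duration_op = d["op"]
        duration_bound = parse_duration(d["value"])
    aggs = []
    for i, a in enumerate(raw.get("aggregates", [])):
        if not isinstance(a, Mapping) or "op" not in a or "concept" not in a:
            raise SchemaError(f"{path}.aggregates[{i}]", "needs 'op' and 'concept'")
        aggs.append(
            AggregateSpec(
                op=a["op"],
                target_concept=a["concept"],
                formula_name=a.get("formula"),
                name=a.get("name"),
            )
        )
    try:
        return EntitySpec(
            name=name,
            type=raw["type"],
            concept=raw.get("concept"),
            condition=_parse_condition(raw.get("condition"), f"{path}.condition"),
            max_gap=_maybe_duration(raw.get("max_gap")),
            min_duration=_maybe_duration(raw.get("min_duration")),
            window=_maybe_duration(raw.get("window")),
            window_aggregate=raw.get("aggregate", "rate"),
            window_min_count=int(raw.get("min_count", 1)),
            external=raw.get("external"),
            start_concept=raw.get("start_concept"),
            end_concept=raw.get("end_concept"),
            pairing=raw.get("pairing", "drop"),
            duration_op=duration_op,
            duration_bound=duration_bound,
            pre=_parse_external(raw["pre"], "pre", f"{path}.pre") if "pre" in raw else None,
            post=_parse_external(raw["post"], "post", f"{path}.post") if "post" in raw else None,
            aggregates=tuple(aggs),
        )
    except VocabularyError:
        raise
    except ConfigError as exc:
        raise SchemaError(path, str(exc)) from None


def _maybe_duration(raw):
    return None if raw is None else parse_duration(raw)


def _parse_node(raw, entities, path) -> PhenotypePattern:
    if isinstance(raw, str):
        if raw not in entities:
            raise SchemaError(path, f"undeclared entity {raw!r}")
        return EntityNode(entities[raw])
    if not isinstance(raw, Mapping):
        raise SchemaError(path, "pattern node must be an entity name or a mapping")
    keys = set(raw)
    if "relation" in keys:
        rel = raw["relation"]
        for k in ("left", "rel", "right"):
            if k not in rel:
                raise SchemaError(f"{path}.relation", f"missing key {k!r}")
        labels = rel["rel"] if isinstance(rel["rel"], list) else [rel["rel"]]
        for l in labels:
            if l not in _RELATION_NAMES:
                raise VocabularyError(f"{path}.relation.rel: unknown relation {l!r}")
        try:
            constraint = RelationConstraint(
                labels=frozenset(RelationLabel(l) for l in labels),
                gap_min=_maybe_duration(rel.get("gap_min")),
                gap_max=_maybe_duration(rel.get("gap_max")),
            )
        except ConfigError as exc:
            raise SchemaError(f"{path}.relation", str(exc)) from None
        return BasicNode(
            left=_parse_node(rel["left"], entities, f"{path}.relation.left"),
            constraint=constraint,
            right=_parse_node(rel["right"], entities, f"{path}.relation.right"),
        )
    if "where" in keys:
        where = raw["where"]
        if "pattern" not in raw:
            raise SchemaError(path, "'where' node needs a 'pattern' child")
        if not isinstance(where, Mapping) or "attribute" not in where:
            raise SchemaError(f"{path}.where", "needs 'attribute'")
        return AttributeFilterNode(
            attribute=where["attribute"],
            condition=_parse_condition(where.get("condition"), f"{path}.where.condition"),
            child=_parse_node(raw["pattern"], entities, f"{path}.pattern"),
        )
    ops = keys & {"and", "or", "xor", "not"}
    if len(ops) == 1:
        op = ops.pop()
        raw_children = raw[op]
        if op == "not":
            raw_children = [raw_children] if not isinstance(raw_children, list) else raw_children
        if not isinstance(raw_children, list):
            raise SchemaError(f"{path}.{op}", "children must be a list")
        children = tuple(
            _parse_node(c, entities, f"{path}.{op}[{i}]")
            for i, c in enumerate(raw_children)
        )
        try:
            return BooleanNode(op, children)
        except ConfigError as exc:
            raise SchemaError(f"{path}.{op}", str(exc)) from None
    if keys:
        raise VocabularyError(
            f"{path}: unknown pattern operator(s) {sorted(keys)}; "
            "expected an entity name, 'relation', 'where', or and/or/xor/not"
        )
    raise SchemaError(path, "empty pattern node")


# ---------------------------------------------------------------------------
# serialization (round-trips through parse_pattern)


def serialize_pattern(pattern: PhenotypePattern, name: str = "phenotype") -> dict:
    """Serialize a pattern tree back to a declarative document."""
    entities: dict[str, dict] = {}

    def node_doc(node):
        if isinstance(node, EntityNode):
            entities[node.spec.name] = _entity_doc(node.spec)
            return node.spec.name
        if isinstance(node, BasicNode):
            labels = sorted(l.value for l in node.constraint.labels)
            rel = {
                "left": node_doc(node.left),
                "rel": labels[0] if len(labels) == 1 else labels,
                "right": node_doc(node.right),
            }
            if node.constraint.gap_min is not None:
                rel["gap_min"] = _duration_doc(node.constraint.gap_min)
            if node.constraint.gap_max is not None:
                rel["gap_max"] = _duration_doc(node.constraint.gap_max)
            return {"relation": rel}
        if isinstance(node, BooleanNode):
            children = [node_doc(c) for c in node.children]
            return {node.op: children[0] if node.op == "not" else children}
        if isinstance(node, AttributeFilterNode):
            return {
                "where": {
                    "attribute": node.attribute,
                    "condition": _condition_doc(node.condition),
                },
                "pattern": node_doc(node.child),
            }
        raise ConfigError(f"cannot serialize node {type(node).__name__}")

    doc = {"phenotype": name, "entities": entities}
    if isinstance(pattern, NestedNode):
        doc["pattern"] = node_doc(pattern.outcome)
        doc["nested"] = {"exposure": node_doc(pattern.exposure)}
    else:
        doc["pattern"] = node_doc(pattern)
    return doc


def _condition_doc(cond: Condition):
    if cond.kind == "always":
        return "always"
    if cond.kind == "categorical":
        return {"category": cond.category}
    if cond.kind == "range":
        out = {"op": "between", "lower": cond.lower, "upper": cond.upper}
    else:
        out = {"op": cond.comparator, "value": cond.value}
    if cond.unit is not None:
        out["unit"] = cond.unit
    return out


def _duration_doc(d):
    return d.isoformat() if isinstance(d, pd.Timedelta) else d


def _entity_doc(spec: EntitySpec) -> dict:
    out: dict = {"type": spec.type}
    if spec.concept is not None:
        out["concept"] = spec.concept
    if spec.condition != Condition.always():
        out["condition"] = _condition_doc(spec.condition)
    if spec.max_gap is not None:
        out["max_gap"] = _duration_doc(spec.max_gap)
    if spec.min_duration is not None:
        out["min_duration"] = _duration_doc(spec.min_duration)
    if spec.window is not None:
        out["window"] = _duration_doc(spec.window)
        out["aggregate"] = spec.window_aggregate
        if spec.window_min_count != 1:
            out["min_count"] = spec.window_min_count
    if spec.external is not None:
        out["external"] = spec.external
    if spec.start_concept is not None:
        out["start_concept"] = spec.start_concept
        out["end_concept"] = spec.end_concept
    if spec.pairing != "drop":
        out["pairing"] = spec.pairing
    if spec.duration_op is not None:
        out["duration"] = {"op": spec.duration_op, "value": _duration_doc(spec.duration_bound)}
    if spec.pre is not None:
        out["pre"] = _external_doc(spec.pre)
    if spec.post is not None:
        out["post"] = _external_doc(spec.post)
    if spec.aggregates:
        out["aggregates"] = [
            {
                "op": a.op,
                "concept": a.target_concept,
                **({"formula": a.formula_name} if a.formula_name else {}),
                **({"name": a.name} if a.name else {}),
            }
            for a in spec.aggregates
        ]
    return out


def _external_doc(cond: ExternalCondition) -> dict:
    out = {
        "variable": cond.variable,
        "condition": _condition_doc(cond.condition),
    }
    default_transform = "divide_value" if cond.stage == "pre" else "divide_aggregate"
    if cond.transform != default_transform:
        out["transform"] = cond.transform
    if cond.attribute is not None:
        out["attribute"] = cond.attribute
    return out
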