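# Methods

This note documents the semantics the engine commits to, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical/design choices made where more than one convention was
defensible.

## Time, intervals and boundary conventions

Timestamps are ISO-8601 in files and `pandas.Timestamp` internally, with
minute resolution and a single clock — no timezone arithmetic is
performed. All operators also accept plain numbers as times (any totally
ordered, subtractable scalar), which the tests use for unit-free
timelines; for the `rate` aggregate a numeric timeline is read as hours.

Intervals are **closed at both ends**, `[start, end]`, with `end > start`
strictly. One convention is applied everywhere: an instant whose
timestamp equals an interval boundary lies inside it for within-interval
aggregation, point relations use inclusive bound comparisons, and
duration filters use the literal comparator ("at least 48 h" keeps an
exactly-48 h interval). The Allen relations are the standard 13, with
`meets` requiring exact endpoint coincidence; because the 13 predicates
partition all endpoint orderings, the closed-interval convention does not
change any relation's definition, only how instants compare to bounds.

Instants are never coerced to degenerate intervals. A point relates to an
interval through a 5-label reduction (`before, starts, during, finishes,
after`) — a zero-duration entity cannot "meet" — and to another point by
trichotomy. This vocabulary is a convention of this engine, chosen so
that every point/interval configuration has exactly one label.

Units are opaque strings compared exactly. A unit stated on both a
condition and an observation must match; a mismatch raises, it is never
coerced. Silent mg/µg or °C/°F conversion is a patient-safety hazard in a
cohort definition, and no conversion table is shipped.

Duplicate rows (same patient, concept, timestamp, value) are retained —
two boluses in one minute are real — but flagged in the ingestion
validation report; ties at identical timestamps keep input order.

## Abstraction operators

**Instant-based.** Satisfying instants chain into a run while consecutive
gaps are ≤ `max_gap`; each maximal run spans `[first, last]`. `max_gap`
has no universal default and is a required parameter: the clinically
tolerable gap differs per variable (hourly vitals vs 6-hourly labs).
Zero-span runs are always dropped — the interval type demands strictly
positive duration, so an instant-based interval needs at least two
supporting instants at distinct times; `min_duration` tightens this
further but cannot relax it below positive duration.

**Bounded.** Start instants pair greedily with the earliest strictly
subsequent unconsumed end instant, which is the correct pairing for
admission/discharge-style delimiters including interleaved repeat stays.
Unpaired entities are handled per policy (`drop` with a warning record,
`open` closing at a censor time, or `error`); nothing is silently
mispaired or discarded.

**Moving-window.** Windows are anchored at observation times only — a
continuous slide would require a carry-forward imputation model between
observations, which the engine deliberately does not have. The aggregate
over the observations in `[t, t + window]` is one of:

* `rate` — sum of external-normalised values divided by the window length
  in hours (urine mL/h → mL/kg/h needs the patient's body weight);
* `per_instant` — the condition must hold at every observation
  individually;
* `mean` / `sum` — the condition applies to the mean or sum.

Both `rate` and `per_instant` are offered because a criterion like
"< 0.5 mL/kg/h during 6 hours" can be read either way; the choice is part
of the phenotype definition, not guessed by the engine.

A window containing fewer than `window_min_count` observations is
**skipped as unevaluable** (default 1; windows with no observations are
always skipped). This matters for sum-like aggregates: a half-observed
window has a trivially small total and would otherwise masquerade as a
low rate at the end of every observation series. For an hourly-charted
variable and a 6-hour window, `min_count: 6` makes exactly the fully
sampled windows evaluable, and a single satisfying window yields an
interval of exactly the window length. Overlapping or abutting satisfying
windows merge into one episode; the emitted interval is the union span of
the satisfying windows (the union, rather than the anchor span, is the
reported extent — the ambiguity is inherent and this choice is fixed and
documented).

## Calculations

Within-interval aggregates use closed bounds. `count` of an empty set is
0 and `sum` is 0, but `mean`/`min`/`max` and formulas over an empty set
yield *absent* (never 0 — 0 is a valid measurement). Derived quantities
beyond the built-in aggregates go through a registry of named pure
formulas; pulse pressure variation,
PPV(%) = 100 · 2 · (PPmax − PPmin)/(PPmax + PPmin), is the built-in
example, computed over the extreme values of the target concept inside
the interval. The span over which PPmax/PPmin are taken is the caller's
interval choice; the formula itself is windowing-agnostic. A free-form
expression language was deliberately not built: one formula motivates a
registry, not a parser.

External-variable conditions divide by a per-patient scalar either per
instant before abstraction (the transformed value is recorded alongside
the original) or per interval attribute after abstraction. A missing
external variable is an explicit per-patient evaluation error — the
patient is reported as `error`, excluded from both matched and unmatched
counts, never silently passed or failed.

## Pattern evaluation

Basic patterns match existentially: a patient matches
`left — relation — right` iff some pair of materialized entities
satisfies the constraint, and all witnesses are kept as evidence. NOT
negates the patient-level verdict; it does not complement intervals on
the timeline (the source criteria use Boolean operators over criteria,
not timeline complements). Nested queries evaluate the exposure on the
full stream and the outcome only on the exposure-matched sub-stream, so
the nested matched set is a subset of the exposure's by construction.
Evaluation is per-patient independent and deterministic; no randomness
exists outside the synthetic module.

The declarative document is validated by a hand-written recursive
checker rather than a generic schema library so that errors carry the
exact path to the offending node (`pattern.and[1].relation: missing key
'rel'`) and unknown relation/operator names are distinguished as
vocabulary errors. Parsed trees serialize back to documents and re-parse
to equal trees.

## Synthetic scenarios

The generator emulates the event categories of ICU charting — admission
and discharge instants, hourly vitals (body temperature, heart rate) and
urine output, 6-hourly labs (lactate) — with per-patient body weight,
sex and age. Four phenotypes can be planted, each with a matching
built-in definition: oliguria (8 h of urine forced to ~0.3 mL/kg/h),
hypothermia (4 h of temperature ~34 °C), a > 7-day stay, and a single
elevated lactate. Defaults: 50 patients, 25 % prevalence per phenotype,
stays of 2–6 days (8–12 for long-stay carriers), zero dropout.

Values are baseline + Gaussian jitter with hard clips chosen so the
ground truth is exact by construction: baseline urine never falls below
0.7 mL/kg/h and episode urine never rises above 0.40 mL/kg/h (so a fully
sampled 6-h window inside an episode is always below the 0.5 threshold
and no baseline window ever is); baseline temperature never drops below
36 °C and episode temperature never exceeds 34.6 °C; baseline lactate is
capped at 2.2 mmol/L. Missingness is event dropout only, applied after
planting and never to an episode's defining observations or to
admission/discharge events, so planted episodes remain recoverable at
any noise level.

These choices mean a passing recovery test certifies the *engine* —
abstraction, relations, evaluation — not robustness to real-world
messiness: no inter-variable physiology, no drifting baselines, no value
corruption, no borderline values near thresholds, no irregular sampling.
Real data will exercise all of those; the generator deliberately does
not.

## Problem sizes and tolerances

The test suite runs the Allen enumeration exhaustively over integer
endpoints in 0..4 (100 ordered pairs), checks both abstraction operators
against brute-force oracles on 1,000 randomized streams of up to 50
instants (plus derandomized hypothesis cases on adversarial integer
grids), and verifies perfect recovery (sensitivity = specificity = 1.0,
zero errors) on a 200-patient scenario — sizes at which the oracles are
tractable and the whole suite completes in seconds. Floating-point
comparisons in the worked examples use exact arithmetic on round numbers
wherever possible; PPV scale-invariance is checked to a 1e-9 relative
tolerance.

## Known limitations

* No terminology services: concepts are opaque codes, and no
  SNOMED/LOINC/ICD mapping is attempted.
* No free-text criteria, trend abstractions (increasing/decreasing), or
  value imputation/carry-forward semantics.
* No Allen-relation composition tables or constraint propagation; the
  engine classifies and tests relations between materialized entities.
* Universal ("for all pairs") basic-pattern semantics are not offered;
  matching is existential, as inclusion criteria typically are.
* Evaluation is in-memory at desk scale; there is no database back-end
  or SQL generation.
* Nested queries do not re-anchor time; an outcome-within-30-days-of-
  exposure criterion is expressed with an explicit gap-bounded relation
  against the exposure's evidence entity instead.
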