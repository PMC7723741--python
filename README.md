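# tempheno

Temporal-abstraction digital phenotyping for timestamped clinical data.

Observational studies on electronic health records select their cohorts
with *phenotyping algorithms* — rules over clinical events such as
"patients with arterial lactate > 2.5 mmol/L during an ICU stay" or
"oliguria (urinary output < 0.5 mL/kg/hour) sustained over a 6-hour
window". Most of these criteria are temporal, and expressing them in raw
SQL over an event table is notoriously error-prone. `tempheno` is a small
query engine for exactly this job, aimed at clinical researchers and
research engineers building retrospective cohorts from ICU-style data.

## The model

Raw data is a long-format event table (one row = patient, concept code,
timestamp, value, unit) plus a per-patient attribute table (age, sex,
body weight, …). On top of it the engine provides:

* **Temporal entities.** An *instant* is a clinical event with a single
  timestamp and no duration; an *interval* has a start, an end and a
  strictly positive duration. Three abstraction operators produce
  intervals from instants:
  * *instant-based* — a maximal run of condition-satisfying identical
    instants, with inter-instant gaps bounded by `max_gap` (hypothermia
    from repeated low temperatures, "IV fluids > 100 mL/h");
  * *bounded* — delimited by distinct start/end instants
    (admission/discharge → hospitalization), with arithmetic filters such
    as "longer than 7 days";
  * *moving-window* — a condition that must hold over a predefined window
    `[t, t + w]`, anchored at observation times (oliguria over 6 hours).
* **Relations.** Allen's 13 interval–interval relations (`before`,
  `meets`, `overlaps`, `starts`, `during`, `finishes`, `equal` and the six
  converses), a 5-label point–interval calculus, the point–point
  trichotomy, and gap-bounded constraints ("within 48 h of admission").
* **Calculations.** Within-interval aggregates (count, sum, mean, min,
  max, registered formulas — e.g. pulse pressure variation,
  PPV(%) = 100 · 2 · (PPmax − PPmin)/(PPmax + PPmin)), and external-variable
  conditions applied per instant before abstraction (mL/h → mL/kg/h) or
  per interval after it (total dose → mg/kg).
* **Patterns.** Entity–relation–entity basic patterns with existential
  matching, Boolean composition (AND, OR, XOR, NOT over patient-level
  verdicts), non-temporal attribute filters, and nested queries —
  SELECT (outcome phenotype) FROM (exposure cohort). Phenotypes are
  declared in a YAML document and evaluated to per-patient verdicts with
  the matched evidence spans.
* **Synthetic data.** A seeded generator of ICU-style streams (admission/
  discharge, hourly vitals and urine output, 6-hourly labs) with planted,
  exactly recoverable phenotype episodes, so the whole engine is testable
  without any real data.

## Worked example

Detect oliguria — urine output below 0.5 mL/kg/hour over a 6-hour window —
for a 70 kg patient charted hourly at 30 mL/h:

```python
import pandas as pd
from tempheno import AbstractionSpec, Condition, Instant, abstract_moving_window

t0 = pd.Timestamp("2024-01-01")
urine = [Instant("p1", "urine_output", t0 + pd.Timedelta(hours=k), 30.0, "mL")
         for k in range(6)]
spec = AbstractionSpec(
    label="oliguria", source_concept="urine_output",
    condition=Condition.threshold("<", 0.5),
    window=pd.Timedelta("6h"), window_aggregate="rate", window_min_count=6,
)
for iv in abstract_moving_window(urine, spec, external=70.0):
    print(iv.concept, iv.start, "->", iv.end)
```

prints

```
oliguria 2024-01-01 00:00:00 -> 2024-01-01 06:00:00
```

one interval of exactly the 6-hour window: 30 mL/h ÷ 70 kg ≈ 0.43 mL/kg/h
is below the 0.5 threshold (at 40 mL/h ≈ 0.57 nothing is emitted).

The same definition as a declarative phenotype, run from the shell against
a generated scenario:

```sh
tempheno synth --out-dir data --seed 5 --n-patients 30
tempheno validate oliguria.yaml
tempheno run --events data/events.csv --attributes data/attrs.csv \
             --phenotype oliguria.yaml --out cohort.csv
```

```
30 patients: 8 matched, 22 not matched, 0 errors -> cohort.csv
```

where `oliguria.yaml` is

```yaml
phenotype: oliguria
entities:
  oliguria:
    type: moving_window
    concept: urine_output
    window: 6h
    aggregate: rate
    external: body_weight
    min_count: 6
    condition: {op: "<", value: 0.5}
pattern: oliguria
```

The 8 matched patients are exactly the 8 carrying planted oliguria
episodes in `data/truth.csv`; `cohort.csv` lists each patient's verdict
with the evidence span that produced it.

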