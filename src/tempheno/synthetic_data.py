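"""Seeded generator of ICU-style event streams with planted phenotypes.

The generator emulates the event categories a critical-care chart review
encounters — admission/discharge instants, periodically sampled vital
signs and laboratory tests, and weight-dependent outputs — and plants
ground-truth phenotype episodes in a chosen fraction of patients:

* ``oliguria`` — urine output forced below 0.5 mL/kg/h for a sustained
  stretch (detectable by the 6-hour moving-window abstraction);
* ``hypothermia`` — body temperature forced below 35 °C over consecutive
  hourly measurements (instant-based abstraction);
* ``long_stay`` — a hospitalization longer than 7 days (bounded
  abstraction + duration filter);
* ``lactate_high`` — one arterial lactate > 2.5 mmol/L during the stay
  (instant-in-interval basic pattern).

Value models are deliberately simple: a physiological baseline plus
Gaussian jitter, clipped so that non-planted patients can never satisfy a
planted definition and planted episodes always do. The generator's job is
to give the query engine an exactly known answer key, not to simulate
physiology. All randomness flows from a single seed through one generator
instance, so an identical scenario yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .event_model import (
    EventRecord,
    EventStream,
    PatientAttributes,
    Verdict,
    write_attributes,
    write_events,
)
from .patterns import PhenotypePattern, evaluate, parse_pattern

__all__ = [
    "ConfusionCounts",
    "Episode",
    "GroundTruth",
    "PlantSpec",
    "ScenarioSpec",
    "builtin_definition",
    "builtin_phenotypes",
    "generate",
    "recover",
    "write_scenario",
]


#: phenotypes the generator knows how to plant
_PLANTERS = ("oliguria", "hypothermia", "long_stay", "lactate_high")


@dataclass(frozen=True)
class PlantSpec:
    """One planted phenotype: its name, the fraction of patients carrying
    it, and episode parameters (currently the episode length in hours)."""

    name: str
    fraction: float
    episode_hours: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError(f"{self.name}: fraction must be in [0, 1]")
        if self.name not in _PLANTERS:
            raise ConfigError(
                f"unknown phenotype {self.name!r}; known: {sorted(_PLANTERS)}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    Sampling cadences follow ICU charting practice: vital signs and urine
    output hourly, laboratory tests every 6 hours. Stays are 2–6 days
    except for patients planted with ``long_stay`` (8–12 days). ``noise``
    is the probability that any one routine observation is missing from
    the chart (event dropout); the observations that define a planted
    episode, and admission/discharge events, are never dropped, so the
    ground truth stays exact.
    """

    n_patients: int = 50
    seed: int = 0
    start: str = "2024-01-01"
    vitals_cadence: object = pd.Timedelta(hours=1)
    labs_cadence: object = pd.Timedelta(hours=6)
    stay_days: tuple[float, float] = (2.0, 6.0)
    long_stay_days: tuple[float, float] = (8.0, 12.0)
    plants: tuple[PlantSpec, ...] = (
        PlantSpec("oliguria", 0.25, episode_hours=8.0),
        PlantSpec("hypothermia", 0.25, episode_hours=4.0),
        PlantSpec("long_stay", 0.25),
        PlantSpec("lactate_high", 0.25),
    )
    noise: float = 0.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not 0.0 <= self.noise < 1.0:
            raise ConfigError("noise must be in [0, 1)")
        names = [p.name for p in self.plants]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate planted phenotype names")


@dataclass(frozen=True)
class Episode:
    phenotype: str
    start: object
    end: object


@dataclass
class GroundTruth:
    """The answer key: which patients carry which planted episodes."""

    episodes: dict[str, list[Episode]] = field(default_factory=dict)
    phenotype_names: tuple[str, ...] = ()
    patient_ids: tuple[str, ...] = ()

    def labels_for(self, patient_id: str) -> set[str]:
        return {e.phenotype for e in self.episodes.get(patient_id, [])}

    def carriers(self, phenotype: str) -> set[str]:
        return {p for p, eps in self.episodes.items() if any(e.phenotype == phenotype for e in eps)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": pid,
                "phenotype": e.phenotype,
                "episode_start": e.start.isoformat(),
                "episode_end": e.end.isoformat(),
            }
            for pid in self.patient_ids
            for e in self.episodes.get(pid, [])
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "phenotype", "episode_start", "episode_end"]
        )


# ---------------------------------------------------------------------------
# generation


def generate(spec: ScenarioSpec) -> tuple[EventStream, GroundTruth]:
    """Generate an event stream plus its ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    origin = pd.Timestamp(spec.start)
    pids = [f"P{i:04d}" for i in range(spec.n_patients)]

    carriers: dict[str, set[str]] = {}
    for plant in spec.plants:
        k = int(round(plant.fraction * spec.n_patients))
        chosen = rng.choice(spec.n_patients, size=k, replace=False) if k else []
        carriers[plant.name] = {pids[i] for i in sorted(chosen)}
    plant_by_name = {p.name: p for p in spec.plants}

    events: list[EventRecord] = []
    attributes: dict[str, PatientAttributes] = {}
    truth = GroundTruth(phenotype_names=tuple(p.name for p in spec.plants), patient_ids=tuple(pids))

    for pid in pids:
        weight = float(np.round(rng.uniform(50.0, 100.0), 1))
        sex = "F" if rng.random() < 0.5 else "M"
        age = int(rng.integers(18, 91))
        attributes[pid] = PatientAttributes(
            pid,
            {"body_weight": weight, "sex": sex, "age": age},
            {"body_weight": "kg", "age": "years"},
        )

        admit = origin + pd.Timedelta(minutes=int(rng.integers(0, 30 * 24 * 60)))
        lo, hi = (
            spec.long_stay_days if pid in carriers.get("long_stay", ()) else spec.stay_days
        )
        stay = pd.Timedelta(hours=float(np.round(rng.uniform(lo * 24, hi * 24), 0)))
        discharge = admit + stay

        my_episodes: list[Episode] = []
        protected: list[tuple[str, object, object]] = []

        def plan(name, concept):
            plant = plant_by_name[name]
            ep = pd.Timedelta(hours=plant.episode_hours)
            margin = pd.Timedelta(hours=2)
            latest = stay - ep - margin
            if latest < margin:
                raise ConfigError(
                    f"{pid}: planted {name} episode ({ep}) does not fit in stay ({stay})"
                )
            offset_h = int(
                rng.integers(
                    int(margin / pd.Timedelta(hours=1)),
                    int(latest / pd.Timedelta(hours=1)) + 1,
                )
            )
            start = admit + pd.Timedelta(hours=offset_h)
            end = start + ep
            my_episodes.append(Episode(name, start, end))
            protected.append((concept, start, end))
            return start, end

        oli_span = plan("oliguria", "urine_output") if pid in carriers.get("oliguria", ()) else None
        hypo_span = plan("hypothermia", "body_temperature") if pid in carriers.get("hypothermia", ()) else None
        if pid in carriers.get("long_stay", ()):
            my_episodes.append(Episode("long_stay", admit, discharge))

        p_events: list[EventRecord] = [
            EventRecord(pid, "icu_admit", admit),
            EventRecord(pid, "icu_discharge", discharge),
        ]
        grid = _grid(admit, discharge, spec.vitals_cadence)
        lab_grid = _grid(admit, discharge, spec.labs_cadence)

        # body temperature (°C): baseline 37 ± 0.3, never below 36;
        # hypothermia episodes 34 ± 0.2, never above 34.6
        temps = np.clip(np.round(rng.normal(37.0, 0.3, len(grid)), 1), 36.0, 40.0)
        if hypo_span is not None:
            inside = [(hypo_span[0] <= t <= hypo_span[1]) for t in grid]
            low = np.clip(np.round(rng.normal(34.0, 0.2, len(grid)), 1), 32.0, 34.6)
            temps = np.where(inside, low, temps)
        for t, v in zip(grid, temps):
            p_events.append(EventRecord(pid, "body_temperature", t, float(v), "C"))

        # heart rate (bpm): clinically inert filler concept
        rates = np.round(rng.normal(82.0, 9.0, len(grid)), 0)
        for t, v in zip(grid, rates):
            p_events.append(EventRecord(pid, "heart_rate", t, float(v), "bpm"))

        # urine output (mL charted per hour): baseline ~1.0 mL/kg/h,
        # never below 0.7 mL/kg/h; oliguria episodes ~0.3, never above 0.40
        urine = np.clip(
            np.round(weight * rng.normal(1.0, 0.15, len(grid)), 1),
            0.7 * weight,
            2.0 * weight,
        )
        if oli_span is not None:
            inside = [(oli_span[0] <= t <= oli_span[1]) for t in grid]
            low = np.clip(
                np.round(weight * rng.normal(0.30, 0.05, len(grid)), 1),
                0.10 * weight,
                0.40 * weight,
            )
            urine = np.where(inside, low, urine)
        for t, v in zip(grid, urine):
            p_events.append(EventRecord(pid, "urine_output", t, float(v), "mL"))

        # arterial lactate (mmol/L): baseline 1.2 ± 0.4 in [0.4, 2.2];
        # a planted elevation replaces one scheduled sample
        lactates = np.clip(np.round(rng.normal(1.2, 0.4, len(lab_grid)), 2), 0.4, 2.2)
        if pid in carriers.get("lactate_high", ()) and len(lab_grid) > 1:
            idx = int(rng.integers(1, len(lab_grid)))
            lactates[idx] = float(np.round(rng.uniform(3.0, 5.0), 2))
            t_high = lab_grid[idx]
            my_episodes.append(Episode("lactate_high", t_high, t_high))
            protected.append(("lactate", t_high, t_high))
        for t, v in zip(lab_grid, lactates):
            p_events.append(EventRecord(pid, "lactate", t, float(v), "mmol/L"))

        if my_episodes:
            truth.episodes[pid] = sorted(my_episodes, key=lambda e: (e.phenotype,))

        if spec.noise > 0.0:
            kept = []
            for e in p_events:
                if e.concept in ("icu_admit", "icu_discharge") or any(
                    c == e.concept and s <= e.time <= t for c, s, t in protected
                ):
                    kept.append(e)
                elif rng.random() >= spec.noise:
                    kept.append(e)
            p_events = kept
        events.extend(p_events)

    return EventStream(events=events, attributes=attributes), truth


def _grid(start, end, cadence):
    out, t = [], start
    while t <= end:
        out.append(t)
        t = t + cadence
    return out


def write_scenario(spec: ScenarioSpec, out_dir) -> tuple[Path, Path, Path]:
    """Generate and write ``events.csv``, ``attrs.csv`` and ``truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stream, truth = generate(spec)
    events_path = out_dir / "events.csv"
    attrs_path = out_dir / "attrs.csv"
    truth_path = out_dir / "truth.csv"
    write_events(stream, events_path)
    write_attributes(stream.attributes, attrs_path)
    truth.to_frame().to_csv(truth_path, index=False)
    return events_path, attrs_path, truth_path


# ---------------------------------------------------------------------------
# matching phenotype definitions


_DEFINITIONS: dict[str, dict] = {
    "oliguria": {
        "phenotype": "oliguria",
        "entities": {
            "oliguria": {
                "type": "moving_window",
                "concept": "urine_output",
                "window": "6h",
                "aggregate": "rate",
                "external": "body_weight",
                "min_count": 6,
                "condition": {"op": "<", "value": 0.5},
            }
        },
        "pattern": "oliguria",
    },
    "hypothermia": {
        "phenotype": "hypothermia",
        "entities": {
            "hypothermia": {
                "type": "instant_based",
                "concept": "body_temperature",
                "condition": {"op": "<", "value": 35.0, "unit": "C"},
                "max_gap": "2h",
                "min_duration": "2h",
            }
        },
        "pattern": "hypothermia",
    },
    "long_stay": {
        "phenotype": "long_stay",
        "entities": {
            "long_stay": {
                "type": "bounded",
                "start_concept": "icu_admit",
                "end_concept": "icu_discharge",
                "duration": {"op": ">", "value": "7 days"},
            }
        },
        "pattern": "long_stay",
    },
    "lactate_high": {
        "phenotype": "lactate_high",
        "entities": {
            "high_lactate": {
                "type": "instant",
                "concept": "lactate",
                "condition": {"op": ">", "value": 2.5, "unit": "mmol/L"},
            },
            "icu_stay": {
                "type": "bounded",
                "start_concept": "icu_admit",
                "end_concept": "icu_discharge",
            },
        },
        "pattern": {
            "relation": {
                "left": "high_lactate",
                "rel": ["starts", "during", "finishes"],
                "right": "icu_stay",
            }
        },
    },
}


def builtin_phenotypes() -> tuple[str, ...]:
    return tuple(_DEFINITIONS)


def builtin_definition(name: str) -> dict:
    """The declarative definition matching a planted phenotype."""
    if name not in _DEFINITIONS:
        raise ConfigError(f"no builtin definition for {name!r}")
    import copy

    return copy.deepcopy(_DEFINITIONS[name])


# ---------------------------------------------------------------------------
# recovery


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    n_errors: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def recover(
    phenotype_name: str,
    stream: EventStream,
    truth: GroundTruth,
    pattern: PhenotypePattern | None = None,
) -> ConfusionCounts:
    """Compare engine verdicts with planted ground truth.

    ``pattern`` defaults to the builtin definition matching the planted
    phenotype. Patients with an ``error`` verdict count in ``n_errors``
    and are treated as not matched for the confusion counts.
    """
    if phenotype_name not in truth.phenotype_names:
        raise ConfigError(
            f"phenotype {phenotype_name!r} was not planted "
            f"(planted: {sorted(truth.phenotype_names)})"
        )
    if pattern is None:
        pattern = parse_pattern(builtin_definition(phenotype_name))
    result = evaluate(pattern, stream)
    tp = fp = fn = tn = n_err = 0
    actual = truth.carriers(phenotype_name)
    for pid, res in result.results.items():
        predicted = res.verdict is Verdict.MATCHED
        if res.verdict is Verdict.ERROR:
            n_err += 1
            predicted = False
        if pid in actual:
            tp, fn = (tp + 1, fn) if predicted else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if predicted else (fp, tn + 1)
    return ConfusionCounts(tp, fp, fn, tn, n_err)
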