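"""The three interval abstractions, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempheno import (
    AbstractionSpec,
    Condition,
    abstract_bounded,
    abstract_instant_based,
    abstract_moving_window,
    filter_duration,
)
from tempheno.errors import ConfigError, PreconditionError, UnitMismatchError

from conftest import H, hours, instant, stream


# ---------------------------------------------------------------------------
# independent oracles


def oracle_instant_based(instants, spec):
    """Enumerate every candidate [t_i, t_j] span and keep the maximal ones.

    A pair (i, j) of satisfying instants delimits an output interval iff
    all satisfying instants between them chain with gaps <= max_gap, the
    run is not extendable on either side, and the span passes the duration
    rule. O(n^3), by definition rather than by a linear scan.
    """
    sat = [
        i
        for i in instants
        if spec.condition.satisfied(
            i.transformed if i.transformed is not None else i.value, i.unit
        )
    ]
    spans = []
    for i in range(len(sat)):
        for j in range(i, len(sat)):
            run = sat[i : j + 1]
            gaps_ok = all(
                run[k + 1].time - run[k].time <= spec.max_gap
                for k in range(len(run) - 1)
            )
            left_ext = i > 0 and run[0].time - sat[i - 1].time <= spec.max_gap
            right_ext = j < len(sat) - 1 and sat[j + 1].time - run[-1].time <= spec.max_gap
            if not gaps_ok or left_ext or right_ext:
                continue
            span = run[-1].time - run[0].time
            if not span > 0 * span:
                continue
            if spec.min_duration is not None and span < spec.min_duration:
                continue
            spans.append((run[0].time, run[-1].time))
    return sorted(set(spans))


def oracle_moving_window(instants, spec, external=None):
    """Evaluate every anchored window independently, then merge by sweeping
    over a sorted list of satisfied windows."""
    sat = []
    for anchor in instants:
        t0, t1 = anchor.time, anchor.time + spec.window
        inside = [i.value for i in instants if t0 <= i.time <= t1]
        if len(inside) < spec.window_min_count or not all(
            isinstance(v, (int, float)) for v in inside
        ):
            continue
        vals = [v / external if external is not None else v for v in inside]
        agg = spec.window_aggregate
        if agg == "per_instant":
            ok = all(spec.condition.satisfied(v) for v in vals)
        elif agg == "mean":
            ok = spec.condition.satisfied(float(np.mean(vals)))
        elif agg == "sum":
            ok = spec.condition.satisfied(float(np.sum(vals)))
        else:  # rate: per hour of window
            w = spec.window / pd.Timedelta(hours=1) if isinstance(spec.window, pd.Timedelta) else spec.window
            ok = spec.condition.satisfied(float(np.sum(vals)) / w)
        if ok:
            sat.append((t0, t1))
    merged = []
    for t0, t1 in sorted(sat):
        if merged and t0 <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], t1))
        else:
            merged.append((t0, t1))
    return merged


def covered(intervals):
    return sum((iv.end - iv.start for iv in intervals), 0)


def random_stream(rng, n_max=50):
    n = int(rng.integers(1, n_max + 1))
    times = np.sort(rng.choice(np.arange(0, 200) / 2.0, size=n, replace=False))
    values = np.round(rng.normal(50, 30, n), 1)
    return [instant("v", float(t), float(v)) for t, v in zip(times, values)]


# ---------------------------------------------------------------------------
# instant-based


def ib_spec(**kw):
    defaults = dict(
        label="abn",
        source_concept="v",
        condition=Condition.threshold("<", 50),
        max_gap=2.0,
    )
    defaults.update(kw)
    return AbstractionSpec(**defaults)


class TestInstantBased:
    def test_hypothermia_hand_trace(self):
        """Hourly temperatures, < 35 °C at hours 2..5, max_gap 2 h →
        one hypothermia interval [h2, h5]."""
        temps = [36.5, 36.2, 34.8, 34.5, 34.9, 34.2, 36.8, 37.0]
        ins = [instant("temp", float(h), v) for h, v in enumerate(temps)]
        spec = AbstractionSpec(
            label="hypothermia",
            source_concept="temp",
            condition=Condition.threshold("<", 35.0),
            max_gap=2.0,
        )
        out = abstract_instant_based(ins, spec)
        assert [(iv.start, iv.end) for iv in out] == [(2.0, 5.0)]
        assert out[0].kind.value == "instant_based"
        assert len(out[0].support) == 4
        assert out[0].attributes["duration"] == 3.0

    def test_iv_fluids_hand_trace(self):
        """Rates (120, 130, 90, 140) hourly, condition > 100 mL/h,
        max_gap 1 h: runs {h1,h2} and {h4}; only the first has positive
        duration."""
        ins = [
            instant("ivf", t, v)
            for t, v in [(1.0, 120.0), (2.0, 130.0), (3.0, 90.0), (4.0, 140.0)]
        ]
        spec = AbstractionSpec(
            label="high_ivf",
            source_concept="ivf",
            condition=Condition.threshold(">", 100.0),
            max_gap=1.0,
        )
        out = abstract_instant_based(ins, spec)
        assert [(iv.start, iv.end) for iv in out] == [(1.0, 2.0)]

    def test_no_satisfying_instants(self):
        ins = [instant("v", float(t), 100.0) for t in range(5)]
        assert abstract_instant_based(ins, ib_spec()) == []

    def test_single_instant_runs_are_dropped(self):
        out = abstract_instant_based([instant("v", 0.0, 10.0)], ib_spec())
        assert out == []

    def test_min_duration_filters_short_runs(self):
        ins = [instant("v", float(t), 10.0) for t in range(4)]
        assert len(abstract_instant_based(ins, ib_spec(min_duration=3.0))) == 1
        assert abstract_instant_based(ins, ib_spec(min_duration=3.5)) == []

    def test_mixed_concepts_rejected(self):
        with pytest.raises(PreconditionError):
            abstract_instant_based(
                [instant("v", 0.0, 10.0), instant("other", 1.0, 10.0)], ib_spec()
            )

    def test_unit_mismatch_is_a_hard_error(self):
        ins = [instant("v", 0.0, 10.0, unit="mg")]
        spec = ib_spec(condition=Condition.threshold("<", 50, unit="mmol/L"))
        with pytest.raises(UnitMismatchError):
            abstract_instant_based(ins, spec)

    def test_max_gap_is_required(self):
        with pytest.raises(ConfigError):
            abstract_instant_based(
                [instant("v", 0.0, 1.0)], ib_spec(max_gap=None)
            )

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(20240101)
        for _ in range(200):
            ins = random_stream(rng)
            spec = ib_spec(max_gap=float(rng.choice([0.5, 1.0, 2.0, 5.0])))
            got = [(iv.start, iv.end) for iv in abstract_instant_based(ins, spec)]
            assert got == oracle_instant_based(ins, spec)

    def test_output_disjoint_and_ordered(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            out = abstract_instant_based(random_stream(rng), ib_spec())
            for a, b in zip(out, out[1:]):
                assert a.end < b.start

    def test_enlarging_max_gap_never_shrinks_coverage(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ins = random_stream(rng)
            small = covered(abstract_instant_based(ins, ib_spec(max_gap=1.0)))
            large = covered(abstract_instant_based(ins, ib_spec(max_gap=3.0)))
            assert large >= small

    def test_tightening_threshold_never_grows_coverage(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            ins = random_stream(rng)
            loose = covered(
                abstract_instant_based(ins, ib_spec(condition=Condition.threshold("<", 60)))
            )
            tight = covered(
                abstract_instant_based(ins, ib_spec(condition=Condition.threshold("<", 40)))
            )
            assert tight <= loose

    def test_deterministic(self):
        rng = np.random.default_rng(17)
        ins = random_stream(rng)
        a = abstract_instant_based(ins, ib_spec())
        b = abstract_instant_based(list(ins), ib_spec())
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]


# ---------------------------------------------------------------------------
# bounded


class TestBounded:
    def test_admission_discharge_pairing(self):
        s = stream([("p1", "admit", 0.0), ("p1", "discharge", 10.0)])
        out = abstract_bounded(s, "admit", "discharge")
        assert len(out) == 1
        assert out[0].attributes["duration"] == 10.0

    def test_two_stays_pair_without_crossing(self):
        s = stream(
            [
                ("p1", "admit", 0.0),
                ("p1", "discharge", 5.0),
                ("p1", "admit", 8.0),
                ("p1", "discharge", 12.0),
            ]
        )
        out = abstract_bounded(s, "admit", "discharge")
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 5.0), (8.0, 12.0)]

    def test_discharge_without_admission_dropped_with_warning(self):
        s = stream([("p1", "discharge", 3.0)])
        out = abstract_bounded(s, "admit", "discharge", pairing="drop")
        assert list(out) == []
        assert len(out.warnings) == 1

    def test_unmatched_start_policies(self):
        s = stream([("p1", "admit", 0.0), ("p1", "lactate", 6.0)])
        dropped = abstract_bounded(s, "admit", "discharge", pairing="drop")
        assert list(dropped) == [] and dropped.warnings
        opened = abstract_bounded(s, "admit", "discharge", pairing="open")
        assert [(iv.start, iv.end) for iv in opened] == [(0.0, 6.0)]
        with pytest.raises(PreconditionError):
            abstract_bounded(s, "admit", "discharge", pairing="error")

    def test_greedy_matches_earliest_subsequent_end(self):
        # two admissions before any discharge: first admit takes first discharge
        s = stream(
            [
                ("p1", "admit", 0.0),
                ("p1", "admit", 2.0),
                ("p1", "discharge", 5.0),
                ("p1", "discharge", 9.0),
            ]
        )
        out = abstract_bounded(s, "admit", "discharge")
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 5.0), (2.0, 9.0)]

    def test_per_patient_independence(self):
        s = stream(
            [
                ("p1", "admit", 0.0),
                ("p2", "discharge", 1.0),
                ("p1", "discharge", 4.0),
                ("p2", "admit", 3.0),
                ("p2", "discharge", 6.0),
            ]
        )
        out = abstract_bounded(s, "admit", "discharge")
        assert {(iv.patient_id, iv.start, iv.end) for iv in out} == {
            ("p1", 0.0, 4.0),
            ("p2", 3.0, 6.0),
        }


# ---------------------------------------------------------------------------
# moving window


def mw_spec(**kw):
    defaults = dict(
        label="mw",
        source_concept="v",
        condition=Condition.threshold("<", 0.5),
        window=6.0,
        window_aggregate="rate",
    )
    defaults.update(kw)
    return AbstractionSpec(**defaults)


class TestMovingWindow:
    def test_oliguria_hand_computation(self):
        """70 kg patient, 30 mL urine per hour for 6 consecutive hours:
        30/70 ≈ 0.43 mL/kg/h < 0.5 → one interval of exactly the window."""
        ins = [instant("v", float(t), 30.0) for t in range(6)]
        out = abstract_moving_window(ins, mw_spec(window_min_count=6), external=70.0)
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 6.0)]
        assert out[0].kind.value == "moving_window"

    def test_oliguria_negative_hand_computation(self):
        """Same chart at 40 mL/h ≈ 0.57 mL/kg/h → no interval."""
        ins = [instant("v", float(t), 40.0) for t in range(6)]
        assert abstract_moving_window(ins, mw_spec(window_min_count=6), external=70.0) == []

    def test_single_satisfying_window_has_window_length(self):
        ins = [instant("v", 0.0, 1.0), instant("v", 3.0, 1.0)]
        spec = mw_spec(
            condition=Condition.threshold("<", 1.0), window=4.0, window_min_count=2
        )
        out = abstract_moving_window(ins, spec, external=10.0)
        # only the window anchored at t=0 contains both instants
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 4.0)]
        assert out[0].end - out[0].start == 4.0

    def test_overlapping_windows_merge(self):
        ins = [instant("v", float(t), 1.0) for t in range(10)]
        spec = mw_spec(condition=Condition.threshold("<", 1.0), window=3.0)
        out = abstract_moving_window(ins, spec, external=10.0)
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 12.0)]

    def test_rate_requires_external_scalar(self):
        with pytest.raises(ConfigError):
            abstract_moving_window([instant("v", 0.0, 1.0)], mw_spec(), external=None)

    def test_undersampled_windows_are_skipped(self):
        ins = [instant("v", 0.0, 1.0)]
        spec = mw_spec(condition=Condition.threshold("<", 1.0), window=6.0,
                       window_min_count=2)
        assert abstract_moving_window(ins, spec, external=10.0) == []

    def test_per_instant_aggregate(self):
        ins = [instant("v", float(t), v) for t, v in enumerate([30.0, 30.0, 40.0])]
        spec = mw_spec(window_aggregate="per_instant", window=1.0)
        out = abstract_moving_window(ins, spec, external=70.0)
        # windows [0,1] ok; [1,2] contains 40/70 = 0.57 -> fails; [2,3] fails
        assert [(iv.start, iv.end) for iv in out] == [(0.0, 1.0)]

    def test_agrees_with_anchored_window_oracle(self):
        rng = np.random.default_rng(20240202)
        for _ in range(200):
            ins = random_stream(rng)
            spec = mw_spec(
                window=float(rng.choice([2.0, 4.0, 6.0])),
                window_aggregate=str(rng.choice(["rate", "mean", "sum", "per_instant"])),
                window_min_count=int(rng.integers(1, 4)),
                condition=Condition.threshold("<", float(rng.integers(20, 90))),
            )
            ext = float(rng.uniform(0.5, 2.0))
            got = [(iv.start, iv.end) for iv in abstract_moving_window(ins, spec, ext)]
            assert got == oracle_moving_window(ins, spec, ext)

    def test_output_disjoint(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            out = abstract_moving_window(random_stream(rng), mw_spec(), external=1.0)
            for a, b in zip(out, out[1:]):
                assert a.end < b.start

    def test_timedelta_windows(self):
        ins = [
            instant("v", hours(k), 30.0) for k in range(6)
        ]
        spec = mw_spec(window=pd.Timedelta("6h"), window_min_count=6)
        out = abstract_moving_window(ins, spec, external=70.0)
        assert [(iv.start, iv.end) for iv in out] == [(hours(0), hours(6))]


# ---------------------------------------------------------------------------
# duration filters


class TestFilterDuration:
    def test_hospitalization_longer_than_7_days(self):
        ivs = [
            stream_interval(0.0, d * 24.0) for d in (3.0, 8.0, 10.0)
        ]
        out = filter_duration(ivs, ">", 7 * 24.0)
        assert [iv.duration for iv in out] == [8 * 24.0, 10 * 24.0]

    def test_greater_than_zero_keeps_all(self):
        ivs = [stream_interval(0.0, 1.0), stream_interval(5.0, 5.5)]
        assert filter_duration(ivs, ">", 0.0) == ivs

    def test_at_least_48h_is_inclusive(self):
        ivs = [stream_interval(0.0, 48.0)]
        assert filter_duration(ivs, ">=", 48.0) == ivs
        assert filter_duration(ivs, ">", 48.0) == []


def stream_interval(start, end):
    from conftest import interval

    return interval(start, end)


# hypothesis property: oracle equivalence on adversarial small streams
@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 40),
            st.floats(0, 100, allow_nan=False, allow_infinity=False),
        ),
        min_size=1,
        max_size=25,
        unique_by=lambda tv: tv[0],
    ),
    st.sampled_from([1, 2, 4]),
)
def test_instant_based_oracle_property(points, gap):
    ins = [instant("v", float(t), round(v, 1)) for t, v in sorted(points)]
    spec = ib_spec(max_gap=float(gap))
    got = [(iv.start, iv.end) for iv in abstract_instant_based(ins, spec)]
    assert got == oracle_instant_based(ins, spec)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 40),
            st.floats(0.1, 100, allow_nan=False, allow_infinity=False),
        ),
        min_size=1,
        max_size=25,
        unique_by=lambda tv: tv[0],
    ),
    st.sampled_from(["rate", "mean", "sum", "per_instant"]),
    st.sampled_from([2, 5, 8]),
)
def test_moving_window_oracle_property(points, agg, window):
    ins = [instant("v", float(t), round(v, 1)) for t, v in sorted(points)]
    spec = mw_spec(window=float(window), window_aggregate=agg,
                   condition=Condition.threshold("<", 40.0))
    got = [(iv.start, iv.end) for iv in abstract_moving_window(ins, spec, 1.5)]
    assert got == oracle_moving_window(ins, spec, 1.5)
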