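"""Inverse-causality symbol induction and measurer-cascade replay."""

import numpy as np
import pytest

from cogsys import (
    BaselineViolationError,
    Cognizer,
    ConfigError,
    CouplingError,
    Layer,
    Measurer,
    MeasurerCascade,
    SensorSequence,
    World,
    augmented_states,
    cascade_simulate,
    classify_cascade,
    ic_operation,
    ic_sound,
    ic_recursive,
    inverse_causality_holds,
    validate_measurer,
)

FIG6_TRACE = [
    ("a0", "b0", "c0", "d0"),
    ("a0", "b0", "c0", "d0"),
    ("a1", "b0", "c0", "d0"),
    ("a0", "b1", "c0", "d0"),
    ("a0", "b0", "c1", "d0"),
    ("a0", "b0", "c0", "d1"),
    ("a0", "b0", "c0", "d0"),
]


def _measurer(prefix="a", extra=("a1", "a2")):
    return Measurer(name=prefix, states=(f"{prefix}0",) + tuple(extra), baselines=(f"{prefix}0",))


def test_ic_introduces_one_symbol_per_distinct_successor():
    m = _measurer()
    seq = SensorSequence("a", ("a0", "a1", "a0", "a2", "a0", "a1"))
    table = ic_operation(seq, m)
    assert table.entries == {("a0", "a1"): "a0#0", ("a0", "a2"): "a0#1"}
    # symbols are fresh: disjoint from the measurer's states
    assert not set(table.entries.values()) & set(m.states)


def test_identity_successor_gets_a_symbol_by_default():
    m = _measurer(extra=("a1",))
    seq = SensorSequence("a", ("a0", "a0", "a0"))
    table = ic_operation(seq, m)
    assert list(table.entries) == [("a0", "a0")]
    minimal = ic_operation(seq, m, include_identity=False)
    assert not minimal.entries  # no external distinction derivable


def test_augmented_sequence_restores_inverse_causality():
    m = _measurer()
    seq = SensorSequence("a", ("a0", "a0", "a1", "a0", "a2", "a0", "a0"))
    table = ic_operation(seq, m)
    assert len(table.symbols_for("a0")) == 3  # a0->a0, a0->a1, a0->a2
    assert ic_sound(seq, m, table)
    # the raw sequence itself violates it (same a0, different successors)
    assert not inverse_causality_holds(seq.states)
    # a deliberately merged table is caught by the scan
    merged = dict(table.entries)
    merged[("a0", "a1")] = merged[("a0", "a2")]
    from cogsys import SymbolTable

    assert not ic_sound(seq, m, SymbolTable(entries=merged))


def test_ic_soundness_oracle_on_random_sequences():
    """Brute-force contrapositive scan passes on 100 random fixtures."""
    rng = np.random.default_rng(23)
    m = Measurer(name="a", states=("a0", "a1", "a2", "a3"), baselines=("a0",))
    for _ in range(100):
        # random baseline-departure/relaxation walk
        states = ["a0"]
        for _ in range(int(rng.integers(3, 30))):
            if states[-1] == "a0":
                states.append(str(rng.choice(("a0", "a1", "a2", "a3"))))
            else:
                states.append("a0")
        seq = SensorSequence("a", tuple(states))
        table = ic_operation(seq, m)
        # symbol count identity: one symbol per distinct observed successor
        observed = {b for a, b in seq.transitions() if a == "a0"}
        assert len(table.entries) == len(observed)
        assert ic_sound(seq, m, table)
        aug = augmented_states(seq, m, table)
        assert not set().union(*(set(a[1:]) for a in aug)) & set(m.states)


def test_departure_from_undeclared_state_is_a_baseline_violation():
    m = _measurer(extra=("a1",))
    seq = SensorSequence("a", ("a0", "a1", "zz", "a0"))
    with pytest.raises(BaselineViolationError, match="IC undefined"):
        ic_operation(seq, m)


def test_multiple_baselines_are_analyzed_separately():
    """Methylation-style declared baseline set: departures grouped per
    baseline, never merged."""
    m = Measurer(name="a", states=("a0", "a0m", "up"), baselines=("a0", "a0m"))
    seq = SensorSequence("a", ("a0", "up", "a0m", "up", "a0m", "a0m"))
    table = ic_operation(seq, m)
    assert table.symbols_for("a0") == ["a0#0"]
    assert set(table.symbols_for("a0m")) == {"a0m#0", "a0m#1"}
    report = validate_measurer(seq, m)
    assert report.ic_valid
    assert set(report.successor_inventory["a0m"]) == {"up", "a0m"}


def test_validate_measurer_flags_shifting_unreturned_baseline():
    m = _measurer()
    good = validate_measurer(SensorSequence("a", ("a0", "a1", "a0", "a2", "a0")), m)
    assert good.ic_valid
    assert set(good.successor_inventory["a0"]) == {"a1", "a2"}
    # departure from a non-baseline a1 (stuck deviation) is a return violation
    bad = validate_measurer(SensorSequence("a", ("a0", "a1", "a2", "a0")), m)
    assert not bad.ic_valid
    assert bad.baseline_return_violations == [(1, "a1")]
    # an undeclared shifted baseline is reported as such
    shifted = validate_measurer(SensorSequence("a", ("a0", "a1", "a0x", "a2")), m)
    assert not shifted.ic_valid
    assert shifted.undeclared_departures == [(2, "a0x", "a2")]


def test_fig6_cascade_trace_is_exact(abcd_cascade):
    traj = cascade_simulate(abcd_cascade, [(2, "a0", "a1")], steps=6)
    assert traj.flat() == FIG6_TRACE


def test_fig6_cascade_encoded_as_a_world_steps_identically():
    """The same chain written as cognition tables: each layer reads the one
    above it; stepping the joint state reproduces the printed wave."""
    def layer_fn(i, hi):
        def f(u):
            prefix = "abcd"[i]
            if i == 0:
                return prefix + "0"  # data: nothing inside entails the sensor
            return prefix + ("1" if u[i - 1] == "abcd"[i - 1] + "1" else "0")
        return f

    cogs = [
        Cognizer("abcd"[i], ("abcd"[i] + "0", "abcd"[i] + "1"), fn=layer_fn(i, None))
        for i in range(4)
    ]
    w = World(cogs)
    assert w.step(("a1", "b0", "c0", "d0")) == ("a0", "b1", "c0", "d0")
    t = w.trajectory(("a1", "b0", "c0", "d0"), 4)
    assert list(t.states) == FIG6_TRACE[2:]


def test_quiescence_without_sensor_events(abcd_cascade):
    traj = cascade_simulate(abcd_cascade, [], steps=8)
    assert all(u == FIG6_TRACE[0] for u in traj.flat())


def test_two_events_make_two_nonoverlapping_waves(abcd_cascade):
    traj = cascade_simulate(
        abcd_cascade, [(2, "a0", "a1"), (5, "a0", "a1")], steps=9
    )
    flat = traj.flat()
    assert flat[2][0] == "a1" and flat[5][0] == "a1"
    assert flat[5][1] == "b0" and flat[6][1] == "b1"  # second wave follows
    assert flat[8][3] == "d1" and flat[9][3] == "d0"
    # each layer shows exactly two pulses, the second a clean 3-step shift
    for k in range(4):
        track = [u[k] for u in flat]
        pulses = [t for t, s in enumerate(track) if s.endswith("1")]
        assert len(pulses) == 2 and pulses[1] - pulses[0] == 3


def test_missing_coupling_entry_is_named(abcd_cascade):
    broken = MeasurerCascade(
        layers=abcd_cascade.layers,
        couplings=({(("a0",), ("a1",)): ("b1",)}, {}, {}),
    )
    with pytest.raises(CouplingError, match="b0.*->.*b1"):
        cascade_simulate(broken, [(2, "a0", "a1")], steps=6)


def test_reader_can_couple_straight_to_effector():
    layers = (
        Layer("A", "sensor", (Measurer("a", ("a0", "a1"), ("a0",), "sensor"),)),
        Layer("B", "reader", (Measurer("b", ("b0", "b1"), ("b0",), "reader"),)),
        Layer("D", "effector", (Measurer("d", ("d0", "d1"), ("d0",), "effector"),)),
    )
    cpl = ({(("a0",), ("a1",)): ("b1",)}, {(("b0",), ("b1",)): ("d1",)})
    abd = MeasurerCascade(layers=layers, couplings=cpl)
    assert classify_cascade(abd) == "well-formed"
    traj = cascade_simulate(abd, [(1, "a0", "a1")], steps=4)
    assert traj.flat() == [
        ("a0", "b0", "d0"),
        ("a1", "b0", "d0"),
        ("a0", "b1", "d0"),
        ("a0", "b0", "d1"),
        ("a0", "b0", "d0"),
    ]


def test_cascade_classification(abcd_cascade):
    assert classify_cascade(abcd_cascade) == "well-formed"
    # a non-measurer in the sensor slot: hallucination-prone
    x = Measurer("x", ("x0", "x1"), baselines=(), role="sensor")
    halluc = MeasurerCascade(
        layers=(Layer("X", "sensor", (x,)),) + abcd_cascade.layers[1:],
        couplings=({(("x0",), ("x1",)): ("b1",)},) + abcd_cascade.couplings[1:],
    )
    assert classify_cascade(halluc) == "hallucination-prone"
    # missing effector: malformed
    chopped = MeasurerCascade(
        layers=abcd_cascade.layers[:3], couplings=abcd_cascade.couplings[:2]
    )
    assert classify_cascade(chopped) == "malformed"


def test_recursive_ic_builds_symbols_level_by_level(abcd_cascade):
    seq_a = SensorSequence("A", ("a0", "a1", "a0", "a0", "a1", "a0"))
    seq_b = SensorSequence("B", ("b0", "b0", "b1", "b0", "b0", "b1"))
    tables = ic_recursive(
        abcd_cascade, {"A": seq_a, "B": seq_b}, include_identity=False
    )
    assert [t.level for t in tables] == ["A->B", "B->C"]
    assert not tables[0].signifies_nonlocal and tables[1].signifies_nonlocal
    assert len(tables[0].entries) == 1 and len(tables[1].entries) == 1
    # symbol counts equal distinct-successor counts at each level (oracle)
    rng = np.random.default_rng(5)
    for _ in range(20):
        states = ["b0"]
        for _ in range(20):
            states.append("b0" if states[-1] != "b0" else str(rng.choice(("b0", "b1"))))
        t = ic_recursive(
            abcd_cascade, {"B": SensorSequence("B", tuple(states))}
        )[0]
        assert len(t.entries) == len({y for x, y in zip(states, states[1:]) if x == "b0"})


def test_forward_backward_consistency():
    """Couplings generated from a symbol table, replayed forward, and re-run
    through the IC operation recover an isomorphic table."""
    sensor = Measurer("a", ("a0", "a1", "a2"), ("a0",), "sensor")
    seq = SensorSequence("a", ("a0", "a1", "a0", "a2", "a0", "a0", "a1", "a0"))
    table = ic_operation(seq, sensor, include_identity=False)
    symbols = tuple(table.entries.values())
    reader = Measurer("b", ("b0",) + symbols, ("b0",), "reader")
    effector = Measurer("d", ("d0", "d1"), ("d0",), "effector")
    cascade = MeasurerCascade(
        layers=(
            Layer("A", "sensor", (sensor,)),
            Layer("B", "reader", (reader,)),
            Layer("D", "effector", (effector,)),
        ),
        couplings=(
            {(("a0",), (s,)): (sym,) for (b, s), sym in table.entries.items()},
            {(("b0",), (sym,)): ("d1",) for sym in symbols},
        ),
    )
    events = [
        (t + 1, frm, to)
        for t, (frm, to) in enumerate(seq.transitions())
        if frm == "a0" and to != "a0"
    ]
    # re-space events so waves do not overlap, preserving their order
    events = [(3 * i + 1, frm, to) for i, (_, frm, to) in enumerate(events)]
    traj = cascade_simulate(cascade, events, steps=3 * len(events) + 2)
    sensor_track = SensorSequence("a", tuple(u[0] for u in traj.flat()))
    recovered = ic_operation(sensor_track, sensor, include_identity=False)
    assert set(recovered.entries) == set(table.entries)  # same (baseline, successor) keys
    # bijective renaming between the symbol sets
    mapping = {table.entries[k]: recovered.entries[k] for k in table.entries}
    assert len(set(mapping.values())) == len(mapping)


def test_measurer_and_layer_validation():
    with pytest.raises(ConfigError):
        Measurer("m", ("s0",), ("nope",))
    with pytest.raises(ConfigError):
        Measurer("m", ("s0",), ("s0",), role="oracle")
    with pytest.raises(ConfigError):
        Layer("L", "sensor", ())
    with pytest.raises(ConfigError, match="undeclared state"):
        MeasurerCascade(
            layers=(
                Layer("A", "sensor", (Measurer("a", ("a0", "a1"), ("a0",)),)),
                Layer("B", "reader", (Measurer("b", ("b0",), ("b0",), "reader"),)),
            ),
            couplings=({(("a0",), ("a1",)): ("b9",)},),
        )
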