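"""Inverse-causality (IC) measurement: symbol induction and measurer cascades.

The unique-successor principle says any element of a deterministic state
sequence has exactly one successor; its contrapositive — distinct successors
imply distinct predecessors — is *inverse causality*.  A sensor that keeps
departing from one baseline state to different states violates inverse
causality on its face: the predecessors are all the same baseline.  The IC
operation repairs this by introducing one fresh internal symbol per distinct
observed successor *behind* the baseline, so that the augmented predecessor
(baseline, symbol) differs whenever the successor differs.  The symbols are
the subject's internal stand-ins for hidden external states: this is how a
system can register an outside world without ever observing it directly.

Replayed forward in time, the same bookkeeping becomes a cascade of
*measurers* — sensor, reader, optional interpreter, effector — each
discriminating the previous layer's state change one step later and then
relaxing back to its baseline.  A measurer may own several baseline states;
IC is computed per departing baseline, never across baselines (a shifting
baseline that is *declared* is adaptation; an undeclared one is a
malfunction that yields no symbols).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import BaselineViolationError, ConfigError, CouplingError

LayerState = tuple[str, ...]
LayerChange = tuple[LayerState, LayerState]

ROLES = ("sensor", "reader", "interpreter", "effector")


@dataclass(frozen=True)
class Measurer:
    """A cognizer with designated baseline state(s) and a return-to-baseline
    contract.  An empty baseline set denotes a non-measurer component (it
    cannot support IC measurement and makes a cascade hallucination-prone
    when placed where the sensor should be)."""

    name: str
    states: tuple[str, ...]
    baselines: tuple[str, ...]
    role: str = "sensor"
    relaxation_window: int = 1

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown measurer role {self.role!r}")
        if len(set(self.states)) != len(self.states):
            raise ConfigError(f"duplicate states in measurer {self.name!r}")
        bad = set(self.baselines) - set(self.states)
        if bad:
            raise ConfigError(f"baselines {sorted(bad)} not in states of {self.name!r}")
        if self.relaxation_window < 1:
            raise ConfigError("relaxation window must be >= 1")

    @property
    def is_measurer(self) -> bool:
        return len(self.baselines) > 0


@dataclass(frozen=True)
class SensorSequence:
    """A measurer's observed state sequence; its step-to-step successor
    relation is the raw material of the IC operation."""

    measurer: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("sensor sequence must be nonempty")

    def transitions(self) -> list[tuple[str, str]]:
        return list(zip(self.states, self.states[1:]))


@dataclass
class SymbolTable:
    """Fresh symbols introduced behind baseline states.

    ``entries`` maps (baseline, observed successor) to the introduced
    symbol.  Symbols are generated as ``<baseline>#<k>`` in first-observation
    order; distinct successors from one baseline always map to distinct
    symbols, and symbols are fresh labels disjoint from the measurer's own
    states.  ``level`` records which coupling produced the table, and
    ``signifies_nonlocal`` marks symbols obtained by recursive IC (they
    stand for states the first-layer sensor cannot detect).
    """

    entries: dict[tuple[str, str], str] = field(default_factory=dict)
    level: str = ""
    signifies_nonlocal: bool = False

    def symbols_for(self, baseline: str) -> list[str]:
        return [s for (b, _), s in sorted(self.entries.items()) if b == baseline]

    def symbol(self, baseline: str, successor: str) -> str:
        return self.entries[(baseline, successor)]


def ic_operation(
    seq: SensorSequence,
    measurer: Measurer,
    include_identity: bool = True,
    level: str = "",
    signifies_nonlocal: bool = False,
) -> SymbolTable:
    """Introduce fresh symbols behind each baseline, one per distinct
    observed successor.

    The identity transition (baseline to itself) receives a symbol by
    default — "nothing changed outside" is itself a registered distinction —
    which ``include_identity=False`` suppresses for minimal tables.
    Transitions departing a declared non-baseline state are relaxation
    returns and are skipped; a transition departing an undeclared state
    makes IC undefined.
    """
    if seq.measurer != measurer.name:
        raise ValueError(
            f"sequence is for {seq.measurer!r}, measurer is {measurer.name!r}"
        )
    baselines = set(measurer.baselines)
    declared = set(measurer.states)
    table = SymbolTable(level=level, signifies_nonlocal=signifies_nonlocal)
    counters = {b: 0 for b in measurer.baselines}
    for x, y in seq.transitions():
        if x not in declared:
            raise BaselineViolationError(
                f"IC undefined: baseline violation (departure from undeclared "
                f"state {x!r} of {measurer.name!r})"
            )
        if x not in baselines:
            continue  # relaxation step; validate_measurer audits its target
        if y not in declared:
            raise BaselineViolationError(
                f"IC undefined: baseline violation (undeclared successor {y!r})"
            )
        if not include_identity and y == x:
            continue
        if (x, y) not in table.entries:
            table.entries[(x, y)] = f"{x}#{counters[x]}"
            counters[x] += 1
    return table


def augmented_states(seq: SensorSequence, measurer: Measurer, table: SymbolTable) -> list[tuple]:
    """The sequence with each baseline occurrence replaced by the pair
    (baseline, introduced symbol for its observed successor).

    On the augmented sequence inverse causality holds by construction:
    distinct successors have distinct predecessors.
    """
    baselines = set(measurer.baselines)
    out: list[tuple] = []
    for i, x in enumerate(seq.states):
        if x in baselines and i + 1 < len(seq.states):
            key = (x, seq.states[i + 1])
            if key in table.entries:
                out.append((x, table.entries[key]))
                continue
        out.append((x,))
    return out


def ic_sound(seq: SensorSequence, measurer: Measurer, table: SymbolTable) -> bool:
    """Exhaustive soundness scan of an IC symbol table.

    On the augmented sequence, distinct raw successors must have distinct
    (baseline, symbol) predecessors; equivalently, each augmented baseline
    state determines its successor.  True by construction for tables built
    by :func:`ic_operation`; this is the independent check.
    """
    aug = augmented_states(seq, measurer, table)
    baselines = set(measurer.baselines)
    succ_of: dict[tuple, str] = {}
    for t in range(len(seq.states) - 1):
        if seq.states[t] not in baselines:
            continue
        key, y = aug[t], seq.states[t + 1]
        if key in succ_of and succ_of[key] != y:
            return False
        succ_of[key] = y
    return True


def inverse_causality_holds(states: Sequence) -> bool:
    """Exhaustive contrapositive scan: equal elements must have equal
    successors (equivalently, distinct successors have distinct
    predecessors)."""
    succ: dict = {}
    for x, y in zip(states, states[1:]):
        if x in succ and succ[x] != y:
            return False
        succ[x] = y
    return True


@dataclass(frozen=True)
class Layer:
    """One cascade layer: an ordered bundle of sub-measurers whose joint
    state is the layer state."""

    name: str
    role: str
    submeasurers: tuple[Measurer, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigError(f"unknown layer role {self.role!r}")
        if not self.submeasurers:
            raise ConfigError(f"layer {self.name!r} has no sub-measurers")

    @property
    def baseline(self) -> LayerState:
        """Initial baseline tuple: each sub-measurer's first baseline."""
        return tuple(
            (m.baselines[0] if m.baselines else m.states[0]) for m in self.submeasurers
        )

    def declared(self, state: LayerState) -> bool:
        return len(state) == len(self.submeasurers) and all(
            s in m.states for s, m in zip(state, self.submeasurers)
        )


@dataclass
class MeasurerCascade:
    """Ordered layers coupled so that each layer discriminates the previous
    layer's baseline departures one time step later.

    ``couplings[i]`` maps layer-i state changes to layer-(i+1) states.
    """

    layers: tuple[Layer, ...]
    couplings: tuple[Mapping[LayerChange, LayerState], ...]

    def __post_init__(self) -> None:
        if len(self.couplings) != max(len(self.layers) - 1, 0):
            raise ConfigError(
                f"{len(self.layers)} layers need {len(self.layers) - 1} couplings, "
                f"got {len(self.couplings)}"
            )
        for i, cpl in enumerate(self.couplings):
            up, down = self.layers[i], self.layers[i + 1]
            for (a, b), target in cpl.items():
                for st, who in ((a, up), (b, up), (target, down)):
                    if not who.declared(tuple(st)):
                        raise ConfigError(
                            f"coupling {up.name}->{down.name} references "
                            f"undeclared state {st}"
                        )

    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]


def classify_cascade(cascade: MeasurerCascade) -> str:
    """Structural diagnosis: ``well-formed`` (sensor-reader-[interpreter]-
    effector of valid measurers), ``hallucination-prone`` (the sensor slot is
    occupied by a non-measurer, so its state changes need not reflect
    external states), or ``malformed`` (missing effector, wrong layer order,
    or a broken downstream measurer)."""
    layers = cascade.layers
    if len(layers) < 3 or layers[-1].role != "effector":
        return "malformed"
    roles = [l.role for l in layers]
    if roles not in (
        ["sensor", "reader", "effector"],
        ["sensor", "reader", "interpreter", "effector"],
    ):
        return "malformed"
    if any(
        not m.is_measurer for l in layers[1:] for m in l.submeasurers
    ):
        return "malformed"
    if any(not m.is_measurer for m in layers[0].submeasurers):
        return "hallucination-prone"
    return "well-formed"


@dataclass(frozen=True)
class LayeredTrajectory:
    """Cascade states over time: per step, a tuple of layer state tuples."""

    layer_names: tuple[str, ...]
    states: tuple[tuple[LayerState, ...], ...]

    def flat(self) -> list[tuple[str, ...]]:
        """Each time step flattened to one tuple across all sub-measurers."""
        return [tuple(s for layer in step for s in layer) for step in self.states]

    def layer_track(self, name: str) -> list[LayerState]:
        i = self.layer_names.index(name)
        return [step[i] for step in self.states]


def _normalize_events(
    sensor: Layer, events: Iterable[tuple]
) -> dict[int, LayerChange]:
    out: dict[int, LayerChange] = {}
    for ev in events:
        t, frm, to = ev
        if isinstance(frm, str):
            frm, to = (frm,), (to,)
        frm, to = tuple(frm), tuple(to)
        for st in (frm, to):
            if not sensor.declared(st):
                raise ConfigError(f"sensor event references undeclared state {st}")
        if t in out:
            raise ConfigError(f"two sensor events scheduled at t={t}")
        out[int(t)] = (frm, to)
    return out


def cascade_simulate(
    cascade: MeasurerCascade,
    sensor_events: Iterable[tuple],
    steps: int,
) -> LayeredTrajectory:
    """Forward-time replay of IC measurement.

    The sensor layer changes only when a scheduled event fires (its states
    are *data*: nothing inside the system entails them).  Every downstream
    layer responds one step later to the previous layer's departure from
    baseline, via the declared coupling; a deviated measurer returns to its
    (most recently departed) baseline on the following step.  The effector's
    states are transformations of upstream symbols, not symbols themselves,
    but it relaxes like any measurer.
    """
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    layers = cascade.layers
    events = _normalize_events(layers[0], sensor_events)
    # most recently departed baseline, per layer and sub-measurer
    last_base: list[list[str]] = [list(l.baseline) for l in layers]
    history: list[tuple[LayerState, ...]] = [tuple(l.baseline for l in layers)]
    for t in range(1, steps + 1):
        prev = history[-1]
        new: list[LayerState] = []
        for k, layer in enumerate(layers):
            cur = prev[k]
            if k == 0:
                ev = events.get(t)
                if ev is not None:
                    if ev[0] != cur:
                        raise ConfigError(
                            f"sensor event at t={t} expects state {ev[0]}, "
                            f"sensor is in {cur}"
                        )
                    nxt = ev[1]
                else:
                    nxt = _relax(layer, cur, last_base[0])
            else:
                up_change = _upstream_change(history, k - 1, t)
                if up_change is not None and _is_departure(
                    layers[k - 1], up_change, last_base[k - 1]
                ):
                    target = cascade.couplings[k - 1].get(up_change)
                    if target is None:
                        raise CouplingError(
                            f"no coupling entry for {layers[k - 1].name} change "
                            f"{up_change[0]} -> {up_change[1]} "
                            f"(downstream {layer.name})"
                        )
                    nxt = target
                else:
                    nxt = _relax(layer, cur, last_base[k])
            _track_departure(layer, cur, nxt, last_base[k])
            new.append(nxt)
        history.append(tuple(new))
    return LayeredTrajectory(
        layer_names=tuple(l.name for l in layers), states=tuple(history)
    )


def _upstream_change(
    history: list[tuple[LayerState, ...]], upstream_index: int, t: int
) -> LayerChange | None:
    """The upstream layer's transition completed one step before ``t``."""
    if t < 2:
        return None
    return (history[t - 2][upstream_index], history[t - 1][upstream_index])


def _is_departure(layer: Layer, change: LayerChange, last_base: list[str]) -> bool:
    """A baseline departure: the layer left a baseline tuple for a different
    state (per sub-measurer, only baseline coordinates may move)."""
    frm, to = change
    if frm == to:
        return False
    for f, m in zip(frm, layer.submeasurers):
        if m.baselines and f not in m.baselines:
            return False
    return True


def _relax(layer: Layer, cur: LayerState, last_base: list[str]) -> LayerState:
    """Each deviated sub-measurer returns to its most recent baseline."""
    out = []
    for s, m, b in zip(cur, layer.submeasurers, last_base):
        if m.baselines and s not in m.baselines:
            out.append(b)
        else:
            out.append(s)
    return tuple(out)


def _track_departure(
    layer: Layer, cur: LayerState, nxt: LayerState, last_base: list[str]
) -> None:
    for i, (c, m) in enumerate(zip(cur, layer.submeasurers)):
        if m.baselines and c in m.baselines and nxt[i] != c:
            last_base[i] = c


def ic_recursive(
    cascade: MeasurerCascade,
    sequences: Mapping[str, SensorSequence],
    include_identity: bool = True,
) -> list[SymbolTable]:
    """Apply the IC operation layer by layer up the cascade.

    Layer k's observed sequence yields the symbols realized as layer k+1
    states; tables beyond the first level are marked as signifying nonlocal
    states (states the first-layer sensor cannot detect, reachable only
    through correlations carried by the intermediate symbols).
    """
    tables: list[SymbolTable] = []
    level_idx = 0
    for layer, nxt in zip(cascade.layers, cascade.layers[1:]):
        seq = sequences.get(layer.name)
        if seq is None:
            continue
        if len(layer.submeasurers) != 1:
            raise ConfigError(
                "recursive IC over a multi-sub-measurer layer needs per-"
                "sub-measurer sequences"
            )
        m = layer.submeasurers[0]
        tables.append(
            ic_operation(
                SensorSequence(measurer=m.name, states=seq.states),
                m,
                include_identity=include_identity,
                level=f"{layer.name}->{nxt.name}",
                signifies_nonlocal=level_idx >= 1,
            )
        )
        level_idx += 1
    return tables


@dataclass
class ValidityReport:
    """Audit of a measurer's observed track against its contract."""

    baseline_return_violations: list[tuple[int, str]] = field(default_factory=list)
    undeclared_departures: list[tuple[int, str, str]] = field(default_factory=list)
    successor_inventory: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def ic_valid(self) -> bool:
        return not self.baseline_return_violations and not self.undeclared_departures


def validate_measurer(seq: SensorSequence, measurer: Measurer) -> ValidityReport:
    """Report baseline-return violations (a non-baseline state that does not
    relax to some baseline within the declared window), departures from
    undeclared states, and the per-baseline successor inventory."""
    report = ValidityReport()
    baselines = set(measurer.baselines)
    declared = set(measurer.states)
    w = measurer.relaxation_window
    states = seq.states
    inv: dict[str, list[str]] = {b: [] for b in measurer.baselines}
    for i, x in enumerate(states):
        if x not in declared:
            to = states[i + 1] if i + 1 < len(states) else x
            report.undeclared_departures.append((i, x, to))
            continue
        if x in baselines:
            if i + 1 < len(states):
                y = states[i + 1]
                if y in declared and y not in inv[x]:
                    inv[x].append(y)
            continue
        # non-baseline: must relax within the window (ignore a truncated tail)
        if i + 1 < len(states):
            horizon = states[i + 1 : i + 1 + w]
            if not any(s in baselines for s in horizon):
                report.baseline_return_violations.append((i, x))
    report.successor_inventory = {b: tuple(v) for b, v in inv.items()}
    return report
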