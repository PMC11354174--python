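"""Bacterial chemotaxis as a sensor-reader-effector measurement cascade.

A minimal run-and-tumble cell on a 1-D lattice with discrete ligand levels:

* the receptor (MCP-like sensor) has one baseline per methylation level
  0..M; it departs to ``up`` or ``down`` whenever the ambient ligand level
  differs from its current methylation baseline, and relaxes on the next
  step.  Methylation drifts one unit toward the ambient level with a
  per-step probability (the adaptation rate), shifting the baseline — the
  receptor's memory of the ambient concentration;
* the switch (CheA/CheY-like reader) relays the receptor's departure one
  step later: ``act+`` for a rise, ``act-`` for a fall, returning to
  ``inactive`` afterwards;
* the motor (flagellar effector) runs or tumbles one further step later:
  tumbling is suppressed after ``act+``, promoted after ``act-``, and
  happens at a spontaneous background rate otherwise.  A tumble re-draws
  the heading uniformly from {-1, +1}; a run moves one lattice cell along
  the heading.

Because departures are triggered by *differences* between ambient level and
the methylation baseline, the cell detects changes in concentration, not
the concentration itself: in any uniform field the long-run tumble
frequency settles at the background rate regardless of the level, while a
monotone gradient biases the walk upward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigError
from .ic import Layer, Measurer, MeasurerCascade, SensorSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LigandField:
    """Discrete attractant levels on a 1-D lattice."""

    concentration: Mapping[int, int]

    def __post_init__(self) -> None:
        if not self.concentration:
            raise ConfigError("ligand field must cover at least one position")
        if any(v < 0 for v in self.concentration.values()):
            raise ConfigError("ligand levels must be nonnegative integers")

    @property
    def positions(self) -> tuple[int, int]:
        ks = self.concentration.keys()
        return min(ks), max(ks)

    def level(self, pos: int) -> int:
        lo, hi = self.positions
        if pos < lo or pos > hi:
            logger.warning("position %d outside field [%d, %d]; clamped", pos, lo, hi)
            pos = min(max(pos, lo), hi)
        return self.concentration[pos]


def uniform_field(level: int, width: int = 81) -> LigandField:
    half = width // 2
    return LigandField({p: level for p in range(-half, half + 1)})


def gradient_field(width: int = 81, levels: int = 8) -> LigandField:
    """A monotone staircase gradient rising with position."""
    half = width // 2
    span = 2 * half
    return LigandField(
        {p: int((p + half) * levels / (span + 1)) for p in range(-half, half + 1)}
    )


@dataclass(frozen=True)
class ChemotaxisCell:
    """Receptor, switch and motor assembled as an A-B-D cascade (no
    interpreter: the reader couples straight to the effector)."""

    receptor: Measurer
    switch: Measurer
    motor: Measurer
    methylation_levels: int
    adaptation_rate: float
    tumble_base: float = 0.1
    tumble_up: float = 0.02
    tumble_down: float = 0.9

    @property
    def cascade(self) -> MeasurerCascade:
        m_states = [f"m{l}" for l in range(self.methylation_levels + 1)]
        cpl_ab = {}
        for b in m_states:
            cpl_ab[((b,), ("up",))] = ("act+",)
            cpl_ab[((b,), ("down",))] = ("act-",)
        cpl_bd = {
            (("inactive",), ("act+",)): ("run",),
            (("inactive",), ("act-",)): ("tumble",),
        }
        return MeasurerCascade(
            layers=(
                Layer("A", "sensor", (self.receptor,)),
                Layer("B", "reader", (self.switch,)),
                Layer("D", "effector", (self.motor,)),
            ),
            couplings=(cpl_ab, cpl_bd),
        )


def build_cell(levels: int, adaptation_rate: float, **tumble_rates: float) -> ChemotaxisCell:
    """A cell with methylation baselines 0..``levels`` and the given
    per-step probability of one-unit methylation drift toward the ambient
    ligand level."""
    if levels < 1:
        raise ConfigError("need at least one methylation step (levels >= 1)")
    if not 0.0 <= adaptation_rate <= 1.0:
        raise ConfigError("adaptation_rate must be in [0,1]")
    m_states = tuple(f"m{l}" for l in range(levels + 1))
    receptor = Measurer(
        name="receptor",
        states=m_states + ("up", "down"),
        baselines=m_states,
        role="sensor",
    )
    switch = Measurer(
        name="switch",
        states=("inactive", "act+", "act-"),
        baselines=("inactive",),
        role="reader",
    )
    motor = Measurer(
        name="motor", states=("run", "tumble"), baselines=("run",), role="effector"
    )
    return ChemotaxisCell(
        receptor=receptor,
        switch=switch,
        motor=motor,
        methylation_levels=levels,
        adaptation_rate=adaptation_rate,
        **tumble_rates,
    )


@dataclass
class CellTrack:
    """Per-step record of a simulated cell."""

    positions: list[int] = field(default_factory=list)
    headings: list[int] = field(default_factory=list)
    motor_states: list[str] = field(default_factory=list)
    methylation: list[int] = field(default_factory=list)
    receptor_states: list[str] = field(default_factory=list)
    switch_states: list[str] = field(default_factory=list)

    def tumble_frequency(self, start: int = 0, stop: int | None = None) -> float:
        window = self.motor_states[start:stop]
        if not window:
            raise ValueError("empty window")
        return sum(s == "tumble" for s in window) / len(window)

    def displacement(self) -> int:
        return self.positions[-1] - self.positions[0]

    def receptor_sequence(self) -> SensorSequence:
        return SensorSequence(measurer="receptor", states=tuple(self.receptor_states))


def simulate_cell(
    cell: ChemotaxisCell,
    ligand: LigandField | Callable[[int, int], int],
    steps: int,
    seed: int,
    start_position: int = 0,
) -> CellTrack:
    """Run the cell for ``steps`` steps.

    ``ligand`` is a spatial field, or a callable ``(t, position) -> level``
    for time-varying stimuli (e.g. a step increase on a tethered cell).
    The cell starts adapted to its initial ambient level.  Each step: the
    receptor compares the ambient level with its methylation baseline, the
    switch relays the receptor's departure one step later, and the motor
    responds one step after that; a run moves the cell one lattice cell
    along its heading, a tumble re-draws the heading.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    ambient_at = ligand.level if isinstance(ligand, LigandField) else None
    bounds = ligand.positions if isinstance(ligand, LigandField) else None
    clamped = False
    M = cell.methylation_levels

    def ambient(t: int, pos: int) -> int:
        lvl = ambient_at(pos) if ambient_at is not None else ligand(t, pos)
        return int(lvl)

    pos = start_position
    heading = int(rng.choice((-1, 1)))
    meth = min(max(ambient(0, pos), 0), M)
    receptor = f"m{meth}"
    prev_receptor = receptor
    switch = "inactive"
    prev_switch = switch
    track = CellTrack()
    for t in range(steps):
        lvl = ambient(t, pos)
        # receptor: departure iff ambient mismatches the methylation baseline
        if receptor in ("up", "down"):
            new_receptor = f"m{meth}"  # return to (possibly shifted) baseline
        elif lvl > meth:
            new_receptor = "up"
        elif lvl < meth:
            new_receptor = "down"
        else:
            new_receptor = f"m{meth}"
        # switch: relays the receptor's previous transition
        if prev_receptor not in ("up", "down") and receptor == "up":
            new_switch = "act+"
        elif prev_receptor not in ("up", "down") and receptor == "down":
            new_switch = "act-"
        else:
            new_switch = "inactive"
        # motor: tumble propensity set by the switch one further step back
        if prev_switch == "act+":
            p_tumble = cell.tumble_up
        elif prev_switch == "act-":
            p_tumble = cell.tumble_down
        else:
            p_tumble = cell.tumble_base
        if rng.random() < p_tumble:
            motor = "tumble"
            heading = int(rng.choice((-1, 1)))
        else:
            motor = "run"
            pos += heading
            if bounds is not None and not bounds[0] <= pos <= bounds[1]:
                if not clamped:
                    logger.warning(
                        "position %d outside field %s; clamping to the edge",
                        pos, bounds,
                    )
                    clamped = True
                pos = min(max(pos, bounds[0]), bounds[1])
        # methylation drifts toward the ambient level (adaptation)
        if meth != min(max(lvl, 0), M) and rng.random() < cell.adaptation_rate:
            meth += 1 if lvl > meth else -1
        track.positions.append(pos)
        track.headings.append(heading)
        track.motor_states.append(motor)
        track.methylation.append(meth)
        track.receptor_states.append(new_receptor)
        track.switch_states.append(new_switch)
        prev_receptor, receptor = receptor, new_receptor
        prev_switch, switch = switch, new_switch
    return track


def step_stimulus(pre_level: int, post_level: int, at: int) -> Callable[[int, int], int]:
    """A spatially uniform, temporally stepped stimulus."""

    def f(t: int, pos: int) -> int:
        return post_level if t >= at else pre_level

    return f
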