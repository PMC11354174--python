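"""The ball-box thought experiments as configurable cognizer worlds.

A player repeatedly draws one ball from a box of ten, observes it and puts
it back.  The box wall's transparency governs how well the player can
discriminate the hidden ball configuration; the player's preference ranking
governs which ball they reach for when informed; balls themselves are
cognizers that may evade a grasp; in the numbered variant, knowledge of a
number-to-gift code ("semiotic transparency") governs whether the player
can exploit non-local sign relations.

Each trial is a short run of a deterministic world.  Randomness enters only
through the seeded initial conditions of a trial: the hidden box
configuration (a cyclic rotation of the declared ball list, so every ball
is equally likely at every position) and the state of a ``noise`` cognizer
that freezes the trial's discrete draws (informedness, uninformed reach
position, percept confusion, grasp quantile).  Within a trial every state
change is a deterministic cognition, so the causal principle holds exactly
and external observers (the Laplacian demon) can be attached as
non-influential copy cognizers.

Per-trial phases of the player: ``ready`` -> ``see:<pos>:<tag>`` (percept)
-> ``reach:<pos>`` -> ``grasp:<pos>`` -> ``hold:<ball>`` (or a single
``retry`` at the next-ranked target if the ball slipped) -> ``ready``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Cognizer, JointState, Trajectory, World
from .errors import ConfigError, UndefinedProbabilityError
from .probability import EventCondition, EventDistribution, EventLabeling, Ratio

NO_PERCEPT = "none"  # through-wall percept behind a fully opaque wall

#: default per-ball confusion weights: adjacent hues are confusable
ADJACENT_HUES = frozenset({frozenset({"orange", "red"})})
_KERNEL_CELLS = 6  # resolution of the discretized confusion kernel


@dataclass(frozen=True)
class Ball:
    """One ball: a color, an optional printed number, and how hard it is to
    grasp (0 = passive, 1 = always evades the first attempt)."""

    id: str
    color: str
    number: int | None = None
    grasp_difficulty: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.grasp_difficulty <= 1.0:
            raise ConfigError(f"grasp_difficulty must be in [0,1]: {self}")


@dataclass(frozen=True)
class BoxConfig:
    """The box: its balls, wall transparency, and optional number->gift code."""

    balls: tuple[Ball, ...]
    wall_transparency: float = 0.0
    semiotic_transparency: float = 0.0
    gift_code: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.balls) < 1:
            raise ConfigError("a box needs at least one ball")
        if not 0.0 <= self.wall_transparency <= 1.0:
            raise ConfigError("wall_transparency must be in [0,1]")
        if not 0.0 <= self.semiotic_transparency <= 1.0:
            raise ConfigError("semiotic_transparency must be in [0,1]")
        ids = [b.id for b in self.balls]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate ball ids: {ids}")

    @property
    def colors(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for b in self.balls:
            seen.setdefault(b.color)
        return tuple(seen)


@dataclass(frozen=True)
class Player:
    """A player: a strict preference ranking over colors (or gifts, in the
    numbered variant), discrimination accuracy (defaults to the wall
    transparency), and knowledge of the number->gift code (defaults to the
    box's semiotic transparency)."""

    preference: tuple[str, ...]
    discrimination_accuracy: float | None = None
    code_knowledge: float | None = None
    confusion_kernel: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not self.preference:
            raise ConfigError("preference ranking must be nonempty")
        if len(set(self.preference)) != len(self.preference):
            raise ConfigError("preference ranking must be strict (no repeats)")


@dataclass(frozen=True)
class TrialRecord:
    """One repeated-trial outcome."""

    trial: int
    ball_id: str
    true_color: str
    perceived: str
    event: str
    seed: int


@dataclass(frozen=True)
class ExperimentRun:
    """Trial records plus the per-trial trajectories that produced them."""

    records: tuple[TrialRecord, ...]
    trajectories: tuple[Trajectory, ...]
    seed: int
    demon: bool = False

    def percept_stream(self) -> list[str]:
        """The player-side event log, one outcome label per trial."""
        return [r.event for r in self.records]


def default_confusion_kernel(colors: Sequence[str]) -> dict[str, dict[str, float]]:
    """Per-color misperception weights: weight 2 for the adjacent hue
    (orange<->red), 1 for every other color; the true color is excluded."""
    kernel: dict[str, dict[str, float]] = {}
    for c in colors:
        kernel[c] = {
            o: (2.0 if frozenset({c, o}) in ADJACENT_HUES else 1.0)
            for o in colors
            if o != c
        }
    return kernel


def _allocate_cells(weights: Mapping[str, float], cells: int) -> list[str]:
    """Largest-remainder allocation of kernel weights onto discrete cells."""
    total = sum(weights.values())
    if total <= 0:
        raise ConfigError("confusion kernel weights must be positive")
    quotas = {k: w / total * cells for k, w in weights.items()}
    base = {k: int(q) for k, q in quotas.items()}
    rest = cells - sum(base.values())
    order = sorted(weights, key=lambda k: (-(quotas[k] - base[k]), k))
    for k in order[:rest]:
        base[k] += 1
    out: list[str] = []
    for k in sorted(base):
        out.extend([k] * base[k])
    return out


class Experiment:
    """A ball-box experiment: a box, a player, and the induced world.

    The world's cognizers, in declaration order: ``box`` (the hidden
    configuration, constant within a trial), ``balls`` (may slip out of a
    grasp), ``noise`` (the trial's frozen draws, constant within a trial),
    and ``player``.
    """

    def __init__(self, box: BoxConfig, player: Player, name: str = "experiment") -> None:
        self.box = box
        self.player = player
        self.name = name
        self.n_balls = len(box.balls)
        self.numbered = box.gift_code is not None
        if self.numbered and any(b.number is None for b in box.balls):
            raise ConfigError("a gift code requires every ball to be numbered")
        self.colors = box.colors
        acc = player.discrimination_accuracy
        self.accuracy = box.wall_transparency if acc is None else acc
        know = player.code_knowledge
        self.knowledge = box.semiotic_transparency if know is None else know
        if not 0.0 <= self.accuracy <= 1.0:
            raise ConfigError("discrimination_accuracy must be in [0,1]")
        if not 0.0 <= self.knowledge <= 1.0:
            raise ConfigError("code_knowledge must be in [0,1]")
        self._check_preference()
        kernel = player.confusion_kernel or default_confusion_kernel(self.colors)
        self._kernel_cells = {
            c: (_allocate_cells(kernel[c], _KERNEL_CELLS) if kernel.get(c) else [c] * _KERNEL_CELLS)
            for c in self.colors
        }
        self._build_axes()
        self._build_world()
        self._demon_world: World | None = None

    # -- configuration --------------------------------------------------------

    def _check_preference(self) -> None:
        if self.numbered:
            code = dict(self.box.gift_code or {})
            for b in self.box.balls:
                if b.number not in code:
                    raise ConfigError(f"gift code has no entry for ball number {b.number}")
            gifts = set(code.values())
            if self.player.preference[0] not in gifts:
                raise ConfigError(
                    f"top preference {self.player.preference[0]!r} is not a coded gift"
                )
        else:
            missing = [c for c in self.colors if c not in self.player.preference]
            if missing:
                raise ConfigError(f"preference ranking does not cover colors {missing}")

    def _build_axes(self) -> None:
        """Discrete noise axes actually needed under this configuration."""
        acc, k = self.accuracy, self.knowledge
        perc = (0, 1) if 0 < acc < 1 else ((1,) if acc == 1 else (0,))
        if self.numbered:
            know = (0, 1) if 0 < k < 1 else ((1,) if k == 1 else (0,))
        else:
            know = (1,)
        may_miss = perc != (1,) or know != (1,)
        upos = tuple(range(self.n_balls)) if may_miss else (0,)
        conf = (
            tuple(range(_KERNEL_CELLS))
            if (may_miss and not self.numbered and self.box.wall_transparency > 0
                and len(self.colors) > 1)
            else (0,)
        )
        q = (
            tuple(range(10))
            if any(0 < b.grasp_difficulty < 1 for b in self.box.balls)
            else (0,)
        )
        self._axes: tuple[tuple[str, tuple[int, ...]], ...] = (
            ("perc", perc), ("know", know), ("upos", upos), ("conf", conf), ("q", q),
        )

    def _noise_states(self) -> list[str]:
        combos = itertools.product(*(vals for _, vals in self._axes))
        keys = [k for k, _ in self._axes]
        return [",".join(f"{k}={v}" for k, v in zip(keys, c)) for c in combos]

    @staticmethod
    def _parse_noise(state: str) -> dict[str, int]:
        return {kv.split("=")[0]: int(kv.split("=")[1]) for kv in state.split(",")}

    # -- box geometry ----------------------------------------------------------

    def ball_at(self, rotation: int, pos: int) -> Ball:
        """Position ``pos`` under configuration ``rotation`` holds this ball."""
        return self.box.balls[(pos + rotation) % self.n_balls]

    def _informed_target(self, rotation: int) -> tuple[int, str]:
        """Target position and percept tag for a fully informed reach."""
        if self.numbered:
            code = dict(self.box.gift_code or {})
            by_gift = {g: num for num, g in code.items()}
            for gift in self.player.preference:
                num = by_gift.get(gift)
                if num is None:
                    continue
                for pos in range(self.n_balls):
                    b = self.ball_at(rotation, pos)
                    if b.number == num:
                        return pos, f"n{num}"
            raise ConfigError("no ball matches any preferred gift")
        for color in self.player.preference:
            positions = [
                p for p in range(self.n_balls) if self.ball_at(rotation, p).color == color
            ]
            if positions:
                return min(positions), color
        raise ConfigError("no ball matches any preferred color")

    def _uninformed_tag(self, rotation: int, pos: int, conf: int) -> str:
        """Percept tag for an uninformed reach: the (possibly confused)
        through-wall impression of the targeted ball, or ``none`` behind a
        fully opaque wall."""
        ball = self.ball_at(rotation, pos)
        if self.numbered:
            return f"n{ball.number}"  # numbers are visible through the clear wall
        if self.box.wall_transparency == 0:
            return NO_PERCEPT
        return self._kernel_cells[ball.color][conf % _KERNEL_CELLS]

    def _retry_target(self, rotation: int, pos: int) -> int:
        """After a slip at ``pos``: the best remaining ranked color, else the
        next position along."""
        if not self.numbered:
            attempted = self.ball_at(rotation, pos).color
            ranking = list(self.player.preference)
            if attempted in ranking:
                for color in ranking[ranking.index(attempted) + 1:]:
                    positions = [
                        p
                        for p in range(self.n_balls)
                        if self.ball_at(rotation, p).color == color
                    ]
                    if positions:
                        return min(positions)
        return (pos + 1) % self.n_balls

    # -- cognition functions ----------------------------------------------------

    def _f_player(self, u: JointState) -> str:
        rot = int(u[0][1:])
        noise = self._parse_noise(u[2])
        state = u[3]
        if state == "ready":
            informed = noise["perc"] == 1 and noise["know"] == 1
            if informed:
                # through a clear wall the percept reflects the whole
                # configuration, not just the chosen target
                pos, tag = self._informed_target(rot)
                tag = f"{tag}@c{rot}"
            else:
                pos = noise["upos"]
                tag = self._uninformed_tag(rot, pos, noise["conf"])
            return f"see:{pos}:{tag}"
        if state.startswith("see:"):
            return f"reach:{state.split(':')[1]}"
        if state.startswith("reach:"):
            return f"grasp:{state.split(':')[1]}"
        if state.startswith("grasp:"):
            pos = int(state.split(":")[1])
            if u[1] == f"slip:{pos}":
                return f"retry:{self._retry_target(rot, pos)}"
            return f"hold:{self.ball_at(rot, pos).id}"
        if state.startswith("retry:"):
            pos = int(state.split(":")[1])
            return f"hold:{self.ball_at(rot, pos).id}"
        if state.startswith("hold:"):
            return "ready"
        raise ConfigError(f"unknown player state {state!r}")

    def _f_balls(self, u: JointState) -> str:
        if u[1] != "rest":
            return "rest"  # a slipped ball settles on the next step
        if u[3].startswith("reach:"):
            rot = int(u[0][1:])
            pos = int(u[3].split(":")[1])
            q = self._parse_noise(u[2])["q"]
            if (q + 0.5) / 10.0 < self.ball_at(rot, pos).grasp_difficulty:
                return f"slip:{pos}"
        return "rest"

    # -- world construction -------------------------------------------------------

    def _player_states(self) -> list[str]:
        tags: list[str] = list(self.colors) + [NO_PERCEPT]
        if self.numbered:
            tags += [f"n{b.number}" for b in self.box.balls]
        tags += [f"{t}@c{r}" for t in tags for r in range(self.n_balls)]
        states = ["ready"]
        for p in range(self.n_balls):
            states += [f"see:{p}:{t}" for t in tags]
            states += [f"reach:{p}", f"grasp:{p}", f"retry:{p}"]
        states += [f"hold:{b.id}" for b in self.box.balls]
        return states

    def _build_world(self) -> None:
        rot_states = [f"r{i}" for i in range(self.n_balls)]
        noise_states = self._noise_states()
        ball_states = ["rest"] + [f"slip:{p}" for p in range(self.n_balls)]
        fns = [
            lambda u: u[0],  # box configuration is constant within a trial
            self._f_balls,
            lambda u: u[2],  # the trial's frozen draws
            self._f_player,
        ]
        self.initial_states = [
            (r, "rest", nz, "ready") for r in rot_states for nz in noise_states
        ]
        closure = _closure(fns, self.initial_states)
        cogs = [
            Cognizer("box", rot_states, fn=fns[0]),
            Cognizer("balls", ball_states, fn=fns[1]),
            Cognizer("noise", noise_states, fn=fns[2]),
            Cognizer("player", self._player_states(), fn=fns[3]),
        ]
        self.world = World(cogs, joint_states=closure, name=self.name)

    # -- demon observer -----------------------------------------------------------

    @property
    def demon_world(self) -> World:
        """The same system plus a Laplacian demon: a cognizer that copies the
        entire joint state one step delayed and influences nothing."""
        if self._demon_world is None:
            base = self.world
            enc = "|".join
            fns = [
                (lambda u, c=c: c.successor(u[:-1])) for c in base.cognizers
            ] + [lambda u: enc(u[:-1])]
            initials = [u + ("*",) for u in self.initial_states]
            closure = _closure(fns, initials)
            demon_states = ["*"] + sorted(enc(u) for u in base.joint_states)
            cogs = [
                Cognizer(c.name, c.states, fn=f)
                for c, f in zip(base.cognizers, fns[:-1])
            ] + [Cognizer("demon", demon_states, fn=fns[-1])]
            self._demon_world = World(
                cogs, joint_states=closure, name=f"{self.name}+demon"
            )
        return self._demon_world

    # -- labelings ------------------------------------------------------------------

    def event_label(self, ball: Ball) -> str:
        return f"ball:{ball.number}" if self.numbered else ball.color

    @property
    def outcome_labeling(self) -> EventLabeling:
        """Draw outcomes as the player's events: a ``hold`` arrival is labeled
        by the drawn ball; other state changes are not events."""
        by_id = {b.id: self.event_label(b) for b in self.box.balls}
        return EventLabeling(
            focal="player",
            label_fn=lambda a, b: by_id.get(b.split(":", 1)[1]) if b.startswith("hold:") else None,
        )

    @property
    def reach_labeling(self) -> EventLabeling:
        """The reach-for-a-target cognition, labeled by the percept tag that
        guided it (e.g. ``reach:red``)."""
        return EventLabeling(
            focal="player",
            label_fn=lambda a, b: (
                f"reach:{a.split(':', 2)[2].split('@')[0]}"
                if b.startswith("reach:") and a.startswith("see:")
                else None
            ),
        )

    def reach_condition(self, tag: str | None = None) -> EventCondition:
        """Conditioning cognition "reach for <tag>"; defaults to the player's
        top preference (the preferred color, or the number coding the
        preferred gift)."""
        if tag is None:
            if self.numbered:
                by_gift = {g: n for n, g in dict(self.box.gift_code or {}).items()}
                tag = f"n{by_gift[self.player.preference[0]]}"
            else:
                tag = self.player.preference[0]
        return EventCondition(self.reach_labeling, f"reach:{tag}")

    @property
    def demon_labeling(self) -> EventLabeling:
        """Draw outcomes as the demon's events: the demon's state change is
        labeled when its new state registers the player holding a ball."""
        by_id = {b.id: self.event_label(b) for b in self.box.balls}

        def lab(a: str, b: str) -> str | None:
            if b == "*":
                return None
            player = b.split("|")[3]
            if player.startswith("hold:"):
                return by_id.get(player.split(":", 1)[1])
            return None

        return EventLabeling(focal="demon", label_fn=lab)

    # -- running trials ----------------------------------------------------------------

    def draw_noise(self, rng: np.random.Generator) -> str:
        parts = []
        for name, values in self._axes:
            if len(values) == 1:
                v = values[0]
            elif name == "perc":
                v = int(rng.random() < self.accuracy)
            elif name == "know":
                v = int(rng.random() < self.knowledge)
            else:
                v = int(values[int(rng.integers(len(values)))])
            parts.append(f"{name}={v}")
        return ",".join(parts)

    def _run_trial(self, world: World, u0: JointState, demon: bool) -> Trajectory:
        states = [u0]
        u = u0
        for _ in range(12):
            u = world.step(u)
            states.append(u)
            probe = u[-1].split("|")[3] if demon else u[3]
            if probe.startswith("hold:"):
                return Trajectory(world_ref=world.name, names=world.names, states=tuple(states))
        raise RuntimeError("trial did not reach a draw outcome")

    def run(self, n: int, seed: int, demon: bool = False) -> ExperimentRun:
        """Run ``n`` independently initialized trials; deterministic given
        (configuration, seed)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        world = self.demon_world if demon else self.world
        records: list[TrialRecord] = []
        trajs: list[Trajectory] = []
        by_id = {b.id: b for b in self.box.balls}
        for i in range(n):
            rot = int(rng.integers(self.n_balls))
            noise = self.draw_noise(rng)
            u0: JointState = (f"r{rot}", "rest", noise, "ready")
            if demon:
                u0 = u0 + ("*",)
            traj = self._run_trial(world, u0, demon)
            records.append(self._record(traj, i, seed, by_id, demon))
            trajs.append(traj)
        return ExperimentRun(tuple(records), tuple(trajs), seed=seed, demon=demon)

    def _record(
        self,
        traj: Trajectory,
        trial: int,
        seed: int,
        by_id: Mapping[str, Ball],
        demon: bool,
    ) -> TrialRecord:
        player = [u[3] for u in traj.states]
        see = next(s for s in player if s.startswith("see:"))
        hold = next(s for s in player if s.startswith("hold:"))
        ball = by_id[hold.split(":", 1)[1]]
        return TrialRecord(
            trial=trial,
            ball_id=ball.id,
            true_color=ball.color,
            perceived=see.split(":", 2)[2].split("@")[0],
            event=self.event_label(ball),
            seed=seed,
        )

    # -- exact enumeration ---------------------------------------------------------------

    def enumerate_draws(self) -> EventDistribution:
        """Exact draw distribution by enumerating equiprobable initial
        conditions (classical probability: favorable cases over all cases).

        Requires a configuration without Bernoulli mixing (accuracy and code
        knowledge 0 or 1), so that every initial condition is equally
        probable.
        """
        if 0 < self.accuracy < 1 or 0 < self.knowledge < 1:
            raise ConfigError(
                "exact enumeration needs accuracy and code knowledge in {0, 1}"
            )
        by_id = {b.id: b for b in self.box.balls}
        counts: dict[str, int] = {}
        for u0 in self.initial_states:
            traj = self._run_trial(self.world, u0, demon=False)
            hold = next(s for s in traj.component("player") if s.startswith("hold:"))
            lab = self.event_label(by_id[hold.split(":", 1)[1]])
            counts[lab] = counts.get(lab, 0) + 1
        labels = tuple(sorted(counts))
        return EventDistribution(labels, tuple(counts[k] for k in labels))


def _closure(fns, initials: Iterable[JointState]) -> set[JointState]:
    """Forward closure of the joint dynamics from a set of initial states."""
    seen: set[JointState] = set()
    frontier = [tuple(u) for u in initials]
    seen.update(frontier)
    while frontier:
        nxt = []
        for u in frontier:
            v = tuple(f(u) for f in fns)
            if v not in seen:
                seen.add(v)
                nxt.append(v)
        frontier = nxt
    return seen


# -- canonical configurations -------------------------------------------------------


def standard_color_box(
    wall_transparency: float,
    grasp_difficulty: Mapping[str, float] | None = None,
) -> BoxConfig:
    """The printed box: two orange, three red, and five blue balls."""
    diff = dict(grasp_difficulty or {})
    composition = [("orange", 2), ("red", 3), ("blue", 5)]
    balls = []
    i = 1
    for color, count in composition:
        for _ in range(count):
            balls.append(Ball(id=f"ball{i}", color=color, grasp_difficulty=diff.get(color, 0.0)))
            i += 1
    return BoxConfig(balls=tuple(balls), wall_transparency=wall_transparency)


def numbered_box(gift_code: Mapping[int, str], code_knowledge: float) -> BoxConfig:
    """Ten same-colored balls numbered 1..10 behind a clear wall, with a
    number->gift code of the given semiotic transparency."""
    balls = tuple(
        Ball(id=f"ball{i}", color="white", number=i) for i in range(1, 11)
    )
    return BoxConfig(
        balls=balls,
        wall_transparency=1.0,
        semiotic_transparency=code_knowledge,
        gift_code=dict(gift_code),
    )


DEFAULT_GIFT_CODE: dict[int, str] = {
    1: "bike", 2: "car", 3: "candy", 4: "book", 5: "hat",
    6: "kite", 7: "drum", 8: "lamp", 9: "mug", 10: "pen",
}


def build_experiment(box: BoxConfig, player: Player, name: str = "experiment") -> Experiment:
    """Assemble the cognizer world for a box and a player."""
    return Experiment(box, player, name=name)


def experiment_A() -> Experiment:
    """Opaque box: the player cannot discriminate ball configurations."""
    return Experiment(
        standard_color_box(0.0),
        Player(preference=("red", "orange", "blue")),
        name="experiment-A",
    )


def experiment_B(grasp_difficulty: Mapping[str, float] | None = None) -> Experiment:
    """Transparent box: perfect discrimination, reach for the preferred color."""
    return Experiment(
        standard_color_box(1.0, grasp_difficulty),
        Player(preference=("red", "orange", "blue")),
        name="experiment-B",
    )


def run_trials(experiment: Experiment, n: int, seed: int) -> list[TrialRecord]:
    """Repeated-trial protocol; deterministic given (configuration, seed)."""
    return list(experiment.run(n, seed).records)


def experiment_C(
    transparency: float, n: int, seed: int, player: Player | None = None
) -> EventDistribution:
    """Semi-transparent box: the estimated draw distribution for a
    (by default red-preferring) player with intermediate discrimination."""
    if not 0 < transparency < 1:
        raise ConfigError("experiment C needs transparency strictly in (0,1)")
    player = player or Player(preference=("red", "orange", "blue"))
    exp = Experiment(standard_color_box(transparency), player, name="experiment-C")
    run = exp.run(n, seed)
    counts: dict[str, int] = {}
    for r in run.records:
        counts[r.event] = counts.get(r.event, 0) + 1
    labels = tuple(sorted(counts))
    return EventDistribution(labels, tuple(counts[k] for k in labels))


def experiment_D(
    code_knowledge: float,
    n: int | None = None,
    seed: int | None = None,
    gift_code: Mapping[int, str] | None = None,
    preferred_gift: str = "car",
) -> EventDistribution:
    """Numbered balls behind a clear wall: the draw distribution for a player
    who wants ``preferred_gift`` and knows the number->gift code to degree
    ``code_knowledge``.

    With knowledge 0 or 1 the distribution is computed exactly by
    enumeration; otherwise ``n`` trials are simulated with ``seed``.
    """
    code = dict(gift_code or DEFAULT_GIFT_CODE)
    exp = Experiment(
        numbered_box(code, code_knowledge),
        Player(preference=(preferred_gift,)),
        name="experiment-D",
    )
    if code_knowledge in (0.0, 1.0):
        return exp.enumerate_draws()
    if n is None or seed is None:
        raise ValueError("intermediate code knowledge needs n and seed")
    run = exp.run(n, seed)
    counts: dict[str, int] = {}
    for r in run.records:
        counts[r.event] = counts.get(r.event, 0) + 1
    labels = tuple(sorted(counts))
    return EventDistribution(labels, tuple(counts[k] for k in labels))


@dataclass(frozen=True)
class InternalistEstimate:
    """Ratios computed from a bare percept stream (no world assumed)."""

    p_overall: Ratio
    p_cog: Ratio | None = None


def internalist_estimate(
    percepts: Sequence[str], event: str, condition: str | None = None
) -> InternalistEstimate:
    """First-person estimation from a sequence of percept labels alone.

    No environment is constructed: the relative frequency of ``event``
    among all percepts is the overall probability, and, if ``condition``
    is given, the frequency of ``event`` immediately following a
    ``condition`` percept is the conditional certainty.
    """
    percepts = list(percepts)
    if not percepts:
        raise ValueError("percept sequence must be nonempty")
    num = sum(p == event for p in percepts)
    overall = Ratio(num / len(percepts), num, len(percepts))
    cog = None
    if condition is not None:
        den = sum(1 for i in range(len(percepts) - 1) if percepts[i] == condition)
        if den == 0:
            raise UndefinedProbabilityError(
                "undefined: the conditioning percept never occurs before "
                "another percept"
            )
        cnum = sum(
            1
            for i in range(len(percepts) - 1)
            if percepts[i] == condition and percepts[i + 1] == event
        )
        cog = Ratio(cnum / den, cnum, den)
    return InternalistEstimate(p_overall=overall, p_cog=cog)
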