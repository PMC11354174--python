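"""Internal and external probability, entropy, and amount of information.

Events are subject-dependent: a focal cognizer experiences an event as a
labeled state change of its own, and distinct state changes may carry the
same label (the same event for the subject).  From a trajectory (or a
collection of independently initialized trajectories) two ratio estimators
are computed:

``p_cog``
    the certainty of an event type among all events following a specified
    cognition (state change) of the focal cognizer — conditioning on one
    concrete state pair, or on any transition carrying a condition label;

``p_overall``
    the relative frequency of an event type over all of the focal
    cognizer's labeled state changes, with no conditioning.

The same two estimators applied to a non-influential observer cognizer give
the external variants: one counting engine, two switches (which cognizer is
focal, whether an influence audit is required).  The full ``p_overall``
distribution over the event alphabet is the subject-dependent environment
summary (the umwelt of the focal cognizer in that trajectory).

Entropies are Shannon entropies in bits over these distributions, and the
amount of information is an entropy difference H_before − H_after.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, Union

import numpy as np

from .core import Trajectory, World
from .errors import ObserverInfluenceError, UndefinedProbabilityError

Transition = tuple[str, str]


@dataclass(frozen=True)
class EventLabeling:
    """Many-to-one map from a focal cognizer's state transitions to events.

    If ``default_label`` is a string the labeling is total: every unmapped
    transition carries the default.  If it is ``None``, unmapped transitions
    are not events for this subject and are excluded from all counts (the
    event alphabet is exactly the labels that appear).  ``label_fn`` is an
    optional fallback callable ``(from, to) -> label or None`` consulted
    before the default; it lets a labeling be defined intensionally for
    large state sets (e.g. an observer that copies joint states).
    """

    focal: str
    label_map: Mapping[Transition, str] = field(default_factory=dict)
    default_label: str | None = None
    label_fn: Callable[[str, str], str | None] | None = None

    def label(self, from_state: str, to_state: str) -> str | None:
        got = self.label_map.get((from_state, to_state))
        if got is not None:
            return got
        if self.label_fn is not None:
            got = self.label_fn(from_state, to_state)
            if got is not None:
                return got
        return self.default_label

    @classmethod
    def by_successor(cls, focal: str) -> "EventLabeling":
        """Label every transition by the state it arrives in."""
        return cls(focal=focal, label_fn=lambda a, b: b)


@dataclass(frozen=True)
class CognitionCondition:
    """A concrete state change of the focal cognizer, used as the
    conditioning cognition for ``p_cog``."""

    focal: str
    from_state: str
    to_state: str

    def matches(self, pair: Transition) -> bool:
        return pair == (self.from_state, self.to_state)


@dataclass(frozen=True)
class EventCondition:
    """A conditioning cognition specified as an event label: any focal
    transition carrying ``label`` under ``labeling`` counts as the
    condition.  Lets "reach for the preferred color" act as one cognition
    even when many concrete state pairs realize it."""

    labeling: EventLabeling
    label: str

    @property
    def focal(self) -> str:
        return self.labeling.focal

    def matches(self, pair: Transition) -> bool:
        return self.labeling.label(*pair) == self.label


Condition = Union[CognitionCondition, EventCondition]


@dataclass(frozen=True)
class Ratio:
    """A counting ratio with its supporting counts."""

    value: float
    numerator: int
    denominator: int

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class EventDistribution:
    """Probability distribution over event labels backed by integer counts."""

    labels: tuple[str, ...]
    support_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.support_counts):
            raise ValueError("labels and support_counts must align")
        if any(c < 0 for c in self.support_counts):
            raise ValueError("support counts must be nonnegative")
        if sum(self.support_counts) == 0:
            raise ValueError("event distribution has no counted events")

    @property
    def probs(self) -> np.ndarray:
        counts = np.asarray(self.support_counts, dtype=float)
        return counts / counts.sum()

    def prob(self, label: str) -> float:
        try:
            i = self.labels.index(label)
        except ValueError:
            return 0.0
        return float(self.probs[i])


def _as_trajs(traj: Trajectory | Iterable[Trajectory]) -> list[Trajectory]:
    if isinstance(traj, Trajectory):
        return [traj]
    trajs = list(traj)
    if not trajs:
        raise ValueError("no trajectories given")
    return trajs


def _labeled_stream(
    trajs: list[Trajectory], labeling: EventLabeling
) -> list[list[tuple[Transition, str | None]]]:
    """Per-trajectory lists of (focal transition, label-or-None).

    Transition streams never cross trajectory boundaries: independently
    initialized trials are independent runs of the same world.
    """
    out = []
    for t in trajs:
        pairs = t.transitions(labeling.focal)
        out.append([(p, labeling.label(*p)) for p in pairs])
    return out


def p_overall(
    traj: Trajectory | Iterable[Trajectory],
    labeling: EventLabeling,
    event: str,
) -> Ratio:
    """Relative frequency of ``event`` over all labeled focal transitions."""
    trajs = _as_trajs(traj)
    if all(t.step_count == 0 for t in trajs):
        raise ValueError("p_overall needs at least one transition")
    num = den = 0
    for stream in _labeled_stream(trajs, labeling):
        for _, lab in stream:
            if lab is None:
                continue
            den += 1
            num += lab == event
    if den == 0:
        raise UndefinedProbabilityError(
            "undefined: no labeled focal transitions in the trajectory"
        )
    return Ratio(num / den, num, den)


def p_cog(
    traj: Trajectory | Iterable[Trajectory],
    cond: Condition,
    labeling: EventLabeling,
    event: str,
    lag: int = 1,
) -> Ratio:
    """Certainty of ``event`` among all events following the cognition
    ``cond``.

    Over all times t where the focal transition matches the condition, the
    ``lag``-th event (labeled focal transition) after t is counted; under a
    total labeling this is exactly the transition at t + ``lag``.  A
    condition that never occurs (or occurs only too close to the end of a
    trajectory for a following event to exist) makes the ratio undefined,
    which is distinct from it being 0.
    """
    dist = p_cog_distribution(traj, cond, labeling, lag=lag)
    num = sum(
        c for lab, c in zip(dist.labels, dist.support_counts) if lab == event
    )
    den = sum(dist.support_counts)
    return Ratio(num / den, num, den)


def p_cog_distribution(
    traj: Trajectory | Iterable[Trajectory],
    cond: Condition,
    labeling: EventLabeling,
    lag: int = 1,
) -> EventDistribution:
    """The full conditional event distribution following ``cond``."""
    if cond.focal != labeling.focal:
        raise ValueError(
            f"condition is on {cond.focal!r} but labeling is on {labeling.focal!r}"
        )
    if lag < 1:
        raise ValueError("lag must be >= 1")
    trajs = _as_trajs(traj)
    counts: dict[str, int] = {}
    for stream in _labeled_stream(trajs, labeling):
        for t, (pair, _) in enumerate(stream):
            if not cond.matches(pair):
                continue
            following = [lab for _, lab in stream[t + 1:] if lab is not None]
            if len(following) < lag:
                continue
            lab = following[lag - 1]
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        raise UndefinedProbabilityError(
            "undefined: zero conditioning events (the condition never "
            "occurred with a following event)"
        )
    labels = tuple(sorted(counts))
    return EventDistribution(labels, tuple(counts[k] for k in labels))


def umwelt_summary(
    traj: Trajectory | Iterable[Trajectory], labeling: EventLabeling
) -> EventDistribution:
    """The subject-dependent environment: the full ``p_overall``
    distribution over all event labels experienced by the focal cognizer."""
    trajs = _as_trajs(traj)
    counts: dict[str, int] = {}
    for stream in _labeled_stream(trajs, labeling):
        for _, lab in stream:
            if lab is None:
                continue
            counts[lab] = counts.get(lab, 0) + 1
    if not counts:
        raise UndefinedProbabilityError("no labeled focal transitions")
    labels = tuple(sorted(counts))
    return EventDistribution(labels, tuple(counts[k] for k in labels))


# -- external (observer) variants ---------------------------------------------


def audit_observer(world: World, observer: str) -> None:
    """Verify the observer is non-influential: every other cognizer's table
    is constant in the observer coordinate.

    The model stipulates that the influence of external observers on an
    observed system is irrelevant; this static audit is the checkable
    reading of that stipulation.
    """
    j = world.index(observer)
    groups: dict[tuple, tuple] = {}
    for u in world.joint_states:
        key = u[:j] + u[j + 1:]
        rest = tuple(
            c.successor(u) for i, c in enumerate(world.cognizers) if i != j
        )
        seen = groups.get(key)
        if seen is None:
            groups[key] = rest
        elif seen != rest:
            raise ObserverInfluenceError(
                f"observer is not external: {observer!r} influences the "
                f"system at joint state {key}"
            )


def external_p_overall(
    world: World,
    traj: Trajectory | Iterable[Trajectory],
    labeling: EventLabeling,
    event: str,
) -> Ratio:
    """``p_overall`` computed on an audited non-influential observer."""
    audit_observer(world, labeling.focal)
    return p_overall(traj, labeling, event)


def external_p_cog(
    world: World,
    traj: Trajectory | Iterable[Trajectory],
    cond: Condition,
    labeling: EventLabeling,
    event: str,
    lag: int = 1,
) -> Ratio:
    """``p_cog`` computed on an audited non-influential observer."""
    audit_observer(world, labeling.focal)
    return p_cog(traj, cond, labeling, event, lag=lag)


# -- entropy and amount of information ----------------------------------------


def entropy(dist: EventDistribution | Sequence[float]) -> float:
    """Shannon entropy in bits, H = −Σ p_i log2 p_i with 0·log2 0 := 0."""
    if isinstance(dist, EventDistribution):
        p = dist.probs
    else:
        p = np.asarray(dist, dtype=float)
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def info_amount(h_before: float, h_after: float) -> float:
    """Amount of information I = H_before − H_after, in bits.

    May be negative (an interaction can raise uncertainty); the sign is
    surfaced, not clamped.
    """
    for h in (h_before, h_after):
        if not math.isfinite(h) or h < 0:
            raise ValueError(f"entropies must be finite and nonnegative, got {h}")
    return h_before - h_after
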