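"""Finite deterministic cognizers-system dynamics.

A *cognizer* is a named finite state set together with a total deterministic
*cognition function* mapping the joint state of the world to the cognizer's
own next state.  A *world* is an ordered collection of cognizers; the induced
product map F sends a joint state to the tuple of every cognizer's next
state.  Iterating F from an initial joint state yields a trajectory.  All
randomness in downstream analyses enters only through the choice of initial
joint state; the dynamics themselves are deterministic (the causal
principle: identical joint states have identical successors).

States are opaque string labels with a declared ordering; no numeric
semantics are assumed.  Cognition functions are stored as explicit lookup
tables.  A builder accepts a callable and tabulates it over the world's
joint-state set, so all downstream code sees tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import CausalViolationError, ConfigError, StateError

JointState = tuple[str, ...]


class Cognizer:
    """A named finite state set plus a deterministic cognition function.

    Parameters
    ----------
    name:
        Identifier, unique within a world.
    states:
        Ordered finite collection of state labels.
    table:
        Explicit transition table mapping joint world states (tuples of
        every cognizer's state, in declaration order, including this one)
        to this cognizer's next state.  May be ``None`` if ``fn`` is given;
        the world builder tabulates the callable.
    fn:
        Callable ``joint_state -> next_state`` used for tabulation.
    neighborhood:
        Optional collection of cognizer names this cognizer is allowed to
        depend on (local causation).  ``None`` means unrestricted.  The
        world builder audits that the table is constant in non-neighbor
        coordinates.
    """

    def __init__(
        self,
        name: str,
        states: Sequence[str],
        table: Mapping[JointState, str] | None = None,
        fn: Callable[[JointState], str] | None = None,
        neighborhood: Iterable[str] | None = None,
    ) -> None:
        if not states:
            raise ConfigError(f"cognizer {name!r} has an empty state set")
        if len(set(states)) != len(states):
            raise ConfigError(f"cognizer {name!r} has duplicate state labels")
        if table is None and fn is None:
            raise ConfigError(f"cognizer {name!r} needs a table or a callable")
        self.name = name
        self.states: tuple[str, ...] = tuple(states)
        self._state_set = frozenset(states)
        self._fn = fn
        self.neighborhood = frozenset(neighborhood) if neighborhood is not None else None
        self.table: dict[JointState, str] = {}
        if table is not None:
            for u, s in table.items():
                self._register(tuple(u), s)

    def _register(self, u: JointState, successor: str) -> None:
        if successor not in self._state_set:
            raise ConfigError(
                f"cognizer {self.name!r}: successor {successor!r} of {u} "
                f"is not a declared state"
            )
        old = self.table.get(u)
        if old is not None and old != successor:
            raise CausalViolationError(
                f"cognizer {self.name!r}: two successors registered for "
                f"joint state {u}: {old!r} and {successor!r}"
            )
        self.table[u] = successor

    def successor(self, u: JointState) -> str:
        """Own next state for joint state ``u``, tabulating on demand."""
        got = self.table.get(u)
        if got is None:
            if self._fn is None:
                raise StateError(
                    f"cognizer {self.name!r}: joint state {u} not in table"
                )
            self._register(u, self._fn(u))
            got = self.table[u]
        return got

    def __repr__(self) -> str:  # pragma: no cover
        return f"Cognizer({self.name!r}, {len(self.states)} states)"


class World:
    """An ordered list of cognizers closed under the induced map F.

    ``joint_states`` defaults to the full product of the member state sets.
    A restricted subset may be supplied, in which case the builder verifies
    that F maps the subset into itself.  The environment of a focal
    cognizer is the tuple of all *other* cognizers' states, in declaration
    order.
    """

    def __init__(
        self,
        cognizers: Sequence[Cognizer],
        joint_states: Iterable[JointState] | None = None,
        name: str = "world",
    ) -> None:
        if not cognizers:
            raise ConfigError("a world needs at least one cognizer")
        names = [c.name for c in cognizers]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate cognizer names: {names}")
        self.name = name
        self.cognizers: tuple[Cognizer, ...] = tuple(cognizers)
        self.names: tuple[str, ...] = tuple(names)
        self._index = {n: i for i, n in enumerate(names)}
        if joint_states is None:
            joint = itertools.product(*(c.states for c in cognizers))
            self.joint_states = frozenset(joint)
        else:
            self.joint_states = frozenset(tuple(u) for u in joint_states)
            for u in self.joint_states:
                if len(u) != len(cognizers):
                    raise ConfigError(f"joint state {u} has wrong arity")
                for c, s in zip(cognizers, u):
                    if s not in c._state_set:
                        raise ConfigError(
                            f"joint state {u}: {s!r} is not a state of {c.name!r}"
                        )
        # Tabulate and check closure: F must map joint_states into itself.
        for u in self.joint_states:
            v = self._apply(u)
            if v not in self.joint_states:
                raise ConfigError(
                    f"world not closed: F({u}) = {v} is outside joint_states"
                )
        self._audit_neighborhoods()

    # -- construction audits -------------------------------------------------

    def _apply(self, u: JointState) -> JointState:
        return tuple(c.successor(u) for c in self.cognizers)

    def _audit_neighborhoods(self) -> None:
        violations = self.neighborhood_violations()
        if violations:
            first = violations[0]
            raise ConfigError(
                f"local-causation violation: cognizer {first[0]!r} "
                f"discriminates non-neighbor {first[1]!r} "
                f"(e.g. at joint states {first[2]} vs {first[3]})"
            )

    def neighborhood_violations(self) -> list[tuple[str, str, JointState, JointState]]:
        """Audit declared neighborhoods: each cognition table must be
        constant in every non-neighbor coordinate.  Returns a list of
        (cognizer, non-neighbor, joint_a, joint_b) witnesses."""
        out: list[tuple[str, str, JointState, JointState]] = []
        for i, c in enumerate(self.cognizers):
            if c.neighborhood is None:
                continue
            for j, other in enumerate(self.cognizers):
                if j == i or other.name in c.neighborhood:
                    continue
                # Group joint states by all coordinates except j.
                groups: dict[tuple, tuple[JointState, str]] = {}
                for u in self.joint_states:
                    key = u[:j] + u[j + 1:]
                    succ = c.successor(u)
                    seen = groups.get(key)
                    if seen is None:
                        groups[key] = (u, succ)
                    elif seen[1] != succ:
                        out.append((c.name, other.name, seen[0], u))
                        break
        return out

    # -- dynamics ------------------------------------------------------------

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise StateError(f"no cognizer named {name!r} in world {self.name!r}")

    def step(self, u: JointState) -> JointState:
        """One application of the world map F."""
        u = tuple(u)
        if u not in self.joint_states:
            raise StateError(f"state not in world: {u}")
        return self._apply(u)

    def trajectory(self, u0: JointState, n: int) -> "Trajectory":
        """Iterate F for ``n`` steps from ``u0`` (sequence of length n+1)."""
        if n < 0:
            raise ValueError(f"step count must be nonnegative, got {n}")
        u = tuple(u0)
        if u not in self.joint_states:
            raise StateError(f"state not in world: {u}")
        states = [u]
        for _ in range(n):
            u = self._apply(u)
            states.append(u)
        return Trajectory(world_ref=self.name, names=self.names, states=tuple(states))

    def orbit(self, u0: JointState) -> tuple[list[JointState], list[JointState]]:
        """Transient and cycle of the forward orbit of ``u0``.

        Every orbit over a finite joint-state set enters a cycle within
        ``len(joint_states)`` steps; the return is ``(transient, cycle)``
        with ``transient + cycle`` the orbit up to first repetition.
        """
        u = tuple(u0)
        if u not in self.joint_states:
            raise StateError(f"state not in world: {u}")
        seen: dict[JointState, int] = {}
        path: list[JointState] = []
        while u not in seen:
            seen[u] = len(path)
            path.append(u)
            u = self._apply(u)
        k = seen[u]
        return path[:k], path[k:]

    # -- discriminability / selectivity ---------------------------------------

    def environment_of(self, focal: str, u: JointState) -> tuple[str, ...]:
        """Tuple of all other cognizers' states in declaration order."""
        i = self.index(focal)
        return u[:i] + u[i + 1:]

    def _joint(self, focal: str, own: str, env: tuple[str, ...]) -> JointState:
        i = self.index(focal)
        u = env[:i] + (own,) + env[i:]
        if u not in self.joint_states:
            raise StateError(f"state not in world: {u}")
        return u

    def environment_states(self, focal: str) -> list[tuple[str, ...]]:
        """All environment tuples occurring in the joint-state set."""
        i = self.index(focal)
        envs = {u[:i] + u[i + 1:] for u in self.joint_states}
        return sorted(envs)

    def discriminates(
        self, focal: str, own_state: str, env_a: tuple[str, ...], env_b: tuple[str, ...]
    ) -> bool:
        """True iff the focal cognizer in ``own_state`` takes different
        successors under environment states ``env_a`` and ``env_b``."""
        c = self.cognizers[self.index(focal)]
        if own_state not in c._state_set:
            raise StateError(f"{own_state!r} is not a state of {focal!r}")
        ua = self._joint(focal, own_state, tuple(env_a))
        ub = self._joint(focal, own_state, tuple(env_b))
        return c.successor(ua) != c.successor(ub)

    def discrimination_partition(
        self, focal: str, own_state: str
    ) -> list[frozenset[tuple[str, ...]]]:
        """Equivalence classes of environment states under "same successor".

        Non-discriminated environment states form one uncertainty class.
        The classes partition the environment tuples compatible with
        ``own_state`` in the joint-state set.
        """
        c = self.cognizers[self.index(focal)]
        if own_state not in c._state_set:
            raise StateError(f"{own_state!r} is not a state of {focal!r}")
        i = self.index(focal)
        classes: dict[str, set[tuple[str, ...]]] = {}
        for u in self.joint_states:
            if u[i] != own_state:
                continue
            env = u[:i] + u[i + 1:]
            classes.setdefault(c.successor(u), set()).add(env)
        return [frozenset(v) for _, v in sorted(classes.items())]

    def selected_relation(self, focal: str, chosen_state: str) -> frozenset[tuple]:
        """The relation slice selected by the focal cognizer choosing
        ``chosen_state``: the set of pairs ``(chosen_state, env)`` over all
        compatible environment states.  Full determination of the relation
        requires the environment's own selection; this descriptor only
        narrows the product space to one coordinate slice.
        """
        c = self.cognizers[self.index(focal)]
        if chosen_state not in c._state_set:
            raise StateError(f"{chosen_state!r} is not a state of {focal!r}")
        i = self.index(focal)
        return frozenset(
            (chosen_state, u[:i] + u[i + 1:])
            for u in self.joint_states
            if u[i] == chosen_state
        )


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed sequence of joint world states produced by iterating F."""

    world_ref: str
    names: tuple[str, ...]
    states: tuple[JointState, ...]

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("a trajectory has at least one state")

    @property
    def step_count(self) -> int:
        return len(self.states) - 1

    def pairs(self) -> list[tuple[JointState, JointState]]:
        """Consecutive (state, successor) pairs."""
        return list(zip(self.states, self.states[1:]))

    def component(self, name: str) -> list[str]:
        """The focal cognizer's state sequence."""
        i = self.names.index(name)
        return [u[i] for u in self.states]

    def transitions(self, name: str) -> list[tuple[str, str]]:
        """The focal cognizer's consecutive state pairs."""
        seq = self.component(name)
        return list(zip(seq, seq[1:]))


@dataclass
class ViolationReport:
    """Result of auditing observed transitions against the causal principle."""

    violations: dict[JointState, frozenset[JointState]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_causal_principle(
    transitions: Sequence[tuple[JointState, JointState]],
) -> ViolationReport:
    """Check that no observed joint state has two distinct successors.

    The causal principle is constitutive of the world model: given a state
    of the world, only one succeeding state is determined.  An empty report
    means the observed pairs are consistent with a deterministic map.
    """
    if not transitions:
        raise ValueError("transition list must be nonempty")
    succ: dict[JointState, set[JointState]] = {}
    for u, v in transitions:
        succ.setdefault(tuple(u), set()).add(tuple(v))
    bad = {u: frozenset(vs) for u, vs in succ.items() if len(vs) > 1}
    return ViolationReport(violations=bad)


def tabulate(
    name: str,
    states: Sequence[str],
    fn: Callable[[JointState], str],
    neighborhood: Iterable[str] | None = None,
) -> Cognizer:
    """Convenience builder: a cognizer whose table is filled lazily from a
    callable during world construction."""
    return Cognizer(name, states, fn=fn, neighborhood=neighborhood)


def identity_cognizer(name: str, states: Sequence[str], index: int) -> Cognizer:
    """A cognizer that keeps its current state regardless of the environment
    (coordinate ``index`` of the joint state is its own)."""
    return Cognizer(name, states, fn=lambda u, i=index: u[i])
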