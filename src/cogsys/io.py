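"""Configuration loading/validation, trajectory serialization, fixtures.

Configs are JSON with a ``schema_version`` field, validated by pydantic
models; validation failures are reported as :class:`~cogsys.errors.ConfigError`
with JSON paths to the offending keys.  Joint states are serialized as
``"s1|s2|..."`` in cognizer declaration order.  Trajectories round-trip
losslessly through a TSV dialect (header ``t<TAB><name1><TAB>...``) and a
JSON-lines dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from .core import Cognizer, Trajectory, World
from .errors import ConfigError
from .ic import Layer, Measurer, MeasurerCascade, SensorSequence
from .probability import EventLabeling

SCHEMA_VERSION = 1

SEP = "|"


def join_state(u: Sequence[str]) -> str:
    return SEP.join(u)


def split_state(s: str) -> tuple[str, ...]:
    return tuple(s.split(SEP))


# -- pydantic schemas ----------------------------------------------------------


class CognizerModel(BaseModel):
    name: str
    states: list[str] = Field(min_length=1)
    table: dict[str, str]


class WorldConfigModel(BaseModel):
    schema_version: int = SCHEMA_VERSION
    cognizers: list[CognizerModel] = Field(min_length=1)
    joint_states: list[str] | None = None
    neighborhoods: dict[str, list[str]] | None = None


class LabelEntryModel(BaseModel):
    from_state: str = Field(alias="from")
    to_state: str = Field(alias="to")
    label: str


class LabelingConfigModel(BaseModel):
    schema_version: int = SCHEMA_VERSION
    focal: str
    labels: list[LabelEntryModel]
    default_label: str | None = None


class MeasurerModel(BaseModel):
    name: str
    states: list[str] = Field(min_length=1)
    baselines: list[str]
    relaxation_window: int = 1


class LayerModel(BaseModel):
    name: str
    role: Literal["sensor", "reader", "interpreter", "effector"]
    submeasurers: list[MeasurerModel] = Field(min_length=1)


class CouplingEntryModel(BaseModel):
    from_state: str = Field(alias="from")
    to_state: str = Field(alias="to")
    target: str


class CouplingModel(BaseModel):
    upstream: str
    entries: list[CouplingEntryModel]


class CascadeConfigModel(BaseModel):
    schema_version: int = SCHEMA_VERSION
    layers: list[LayerModel] = Field(min_length=1)
    couplings: list[CouplingModel]


def _load_json(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{p}: invalid JSON: {e}") from e


def _validate(model: type[BaseModel], data: Mapping, source: str) -> BaseModel:
    try:
        return model.model_validate(data)
    except ValidationError as e:
        paths = "; ".join(
            "/".join(str(x) for x in err["loc"]) + ": " + err["msg"]
            for err in e.errors()
        )
        raise ConfigError(f"{source}: schema violation at {paths}") from e


# -- world configs --------------------------------------------------------------


def world_from_config(data: Mapping, source: str = "<config>") -> World:
    cfg = _validate(WorldConfigModel, data, source)
    assert isinstance(cfg, WorldConfigModel)
    neigh = cfg.neighborhoods or {}
    cognizers = []
    for c in cfg.cognizers:
        table = {split_state(k): v for k, v in c.table.items()}
        for k, v in table.items():
            if v not in c.states:
                raise ConfigError(
                    f"{source}: cognizer {c.name!r} maps {join_state(k)!r} to "
                    f"undeclared state {v!r}"
                )
        cognizers.append(
            Cognizer(c.name, c.states, table=table, neighborhood=neigh.get(c.name))
        )
    joint = (
        [split_state(s) for s in cfg.joint_states]
        if cfg.joint_states is not None
        else None
    )
    return World(cognizers, joint_states=joint)


def load_world_config(path: str | Path) -> World:
    return world_from_config(_load_json(path), source=str(path))


def dump_world_config(world: World) -> dict:
    """Serialize a world back to its JSON config form (semantic round-trip)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "cognizers": [
            {
                "name": c.name,
                "states": list(c.states),
                "table": {
                    join_state(u): c.successor(u) for u in sorted(world.joint_states)
                },
            }
            for c in world.cognizers
        ],
        "joint_states": [join_state(u) for u in sorted(world.joint_states)],
        "neighborhoods": {
            c.name: sorted(c.neighborhood)
            for c in world.cognizers
            if c.neighborhood is not None
        } or None,
    }


def labeling_from_config(data: Mapping, source: str = "<config>") -> EventLabeling:
    cfg = _validate(LabelingConfigModel, data, source)
    assert isinstance(cfg, LabelingConfigModel)
    return EventLabeling(
        focal=cfg.focal,
        label_map={(e.from_state, e.to_state): e.label for e in cfg.labels},
        default_label=cfg.default_label,
    )


def load_labeling_config(path: str | Path) -> EventLabeling:
    return labeling_from_config(_load_json(path), source=str(path))


def cascade_from_config(data: Mapping, source: str = "<config>") -> MeasurerCascade:
    cfg = _validate(CascadeConfigModel, data, source)
    assert isinstance(cfg, CascadeConfigModel)
    layers = tuple(
        Layer(
            name=l.name,
            role=l.role,
            submeasurers=tuple(
                Measurer(
                    name=m.name,
                    states=tuple(m.states),
                    baselines=tuple(m.baselines),
                    role=l.role,
                    relaxation_window=m.relaxation_window,
                )
                for m in l.submeasurers
            ),
        )
        for l in cfg.layers
    )
    by_name = {l.name: i for i, l in enumerate(layers)}
    couplings: list[dict] = [{} for _ in range(max(len(layers) - 1, 0))]
    for cp in cfg.couplings:
        i = by_name.get(cp.upstream)
        if i is None or i >= len(layers) - 1:
            raise ConfigError(f"{source}: coupling upstream {cp.upstream!r} unknown")
        for e in cp.entries:
            couplings[i][(split_state(e.from_state), split_state(e.to_state))] = (
                split_state(e.target)
            )
    return MeasurerCascade(layers=layers, couplings=tuple(couplings))


def load_cascade_config(path: str | Path) -> MeasurerCascade:
    return cascade_from_config(_load_json(path), source=str(path))


def load_sensor_events(path: str | Path) -> list[tuple[int, str, str]]:
    """Sensor-event TSV: ``t<TAB>measurer<TAB>from<TAB>to``."""
    events = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("t\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ConfigError(f"{path}:{i}: expected 4 tab-separated fields")
        t, _, frm, to = parts
        events.append((int(t), frm, to))
    return events


def load_percepts(path: str | Path) -> list[str]:
    """Bare percept stream: one label per line."""
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


# -- trajectory serialization -----------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "tsv") -> None:
    p = Path(path)
    if format == "tsv":
        lines = [f"# world_ref={traj.world_ref}", "t\t" + "\t".join(traj.names)]
        for t, u in enumerate(traj.states):
            lines.append(f"{t}\t" + "\t".join(u))
        p.write_text("\n".join(lines) + "\n")
    elif format == "jsonl":
        lines = [json.dumps({"world_ref": traj.world_ref, "names": list(traj.names)})]
        for t, u in enumerate(traj.states):
            lines.append(json.dumps({"t": t, "state": list(u)}))
        p.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: str | Path) -> Trajectory:
    p = Path(path)
    text = p.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if first.startswith("{"):
        return _read_trajectory_jsonl(p, text)
    return _read_trajectory_tsv(p, text)


def _read_trajectory_tsv(p: Path, text: str) -> Trajectory:
    world_ref = "world"
    names: tuple[str, ...] | None = None
    states = []
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("# world_ref="):
            world_ref = line.split("=", 1)[1]
            continue
        parts = line.split("\t")
        if names is None:
            if parts[0] != "t":
                raise ConfigError(f"{p}:{i}: missing 't' header column")
            names = tuple(parts[1:])
            continue
        if len(parts) != len(names) + 1:
            raise ConfigError(
                f"{p}:{i}: expected {len(names) + 1} columns, got {len(parts)}"
            )
        states.append(tuple(parts[1:]))
    if names is None or not states:
        raise ConfigError(f"{p}: empty trajectory file")
    return Trajectory(world_ref=world_ref, names=names, states=tuple(states))


def _read_trajectory_jsonl(p: Path, text: str) -> Trajectory:
    lines = [l for l in text.splitlines() if l.strip()]
    try:
        head = json.loads(lines[0])
        states = [tuple(json.loads(l)["state"]) for l in lines[1:]]
    except (json.JSONDecodeError, KeyError) as e:
        raise ConfigError(f"{p}: malformed JSON-lines trajectory: {e}") from e
    if not states:
        raise ConfigError(f"{p}: empty trajectory file")
    return Trajectory(
        world_ref=head["world_ref"], names=tuple(head["names"]), states=tuple(states)
    )


def write_cell_track(track, path: str | Path) -> None:
    """Chemotaxis track TSV: ``t position heading motor methylation``."""
    lines = ["t\tposition\theading\tmotor\tmethylation"]
    for t in range(len(track.positions)):
        lines.append(
            f"{t}\t{track.positions[t]}\t{track.headings[t]}"
            f"\t{track.motor_states[t]}\t{track.methylation[t]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_ligand_field(path: str | Path):
    """Field TSV: ``position<TAB>level``."""
    from .chemotaxis import LigandField

    levels = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#") or line.startswith("position"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigError(f"{path}:{i}: expected 2 tab-separated fields")
        levels[int(parts[0])] = int(parts[1])
    return LigandField(levels)


# -- seeded fixtures ----------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """A seeded random world: ``n_cognizers`` cognizers with
    ``n_states`` states each; with ``measurers=True`` each cognizer gets a
    designated baseline (its first state) and relaxes to it from every
    non-baseline state, so its tracks honor the measurer contract."""

    n_cognizers: int = 2
    n_states: int = 2
    measurers: bool = False

    def __post_init__(self) -> None:
        if self.n_cognizers < 1 or self.n_states < 1:
            raise ConfigError("fixture sizes must be >= 1")


def generate_fixture(spec: FixtureSpec, seed: int) -> dict:
    """Deterministic random world config; the generated tables are functions
    by construction, so the causal principle holds trivially."""
    import itertools

    rng = np.random.default_rng(seed)
    names = [f"C{i + 1}" for i in range(spec.n_cognizers)]
    statesets = [
        [f"s{i + 1}{chr(ord('a') + j)}" for j in range(spec.n_states)]
        for i in range(spec.n_cognizers)
    ]
    cognizers = []
    for i, (name, states) in enumerate(zip(names, statesets)):
        table = {}
        for u in itertools.product(*statesets):
            if spec.measurers and u[i] != states[0]:
                table[join_state(u)] = states[0]  # relax to baseline
            else:
                table[join_state(u)] = states[int(rng.integers(len(states)))]
        cognizers.append({"name": name, "states": states, "table": table})
    return {"schema_version": SCHEMA_VERSION, "cognizers": cognizers}


def fixture_world(spec: FixtureSpec, seed: int) -> World:
    return world_from_config(generate_fixture(spec, seed), source=f"fixture(seed={seed})")
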