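import pytest

from cogsys import Cognizer, Layer, Measurer, MeasurerCascade, World

W2_CONFIG = {
    "schema_version": 1,
    "cognizers": [
        {
            "name": "C1",
            "states": ["x", "y"],
            "table": {"x|p": "x", "x|q": "y", "y|p": "y", "y|q": "y"},
        },
        {
            "name": "C2",
            "states": ["p", "q"],
            "table": {"x|p": "q", "x|q": "p", "y|p": "p", "y|q": "q"},
        },
    ],
}


@pytest.fixture
def w2() -> World:
    """Two-cognizer toy world with a hand-iterable transition table."""
    from cogsys.io import world_from_config

    return world_from_config(W2_CONFIG)


def single_measurer(prefix: str, role: str, n_states: int = 2) -> Measurer:
    states = tuple(f"{prefix}{i}" for i in range(n_states))
    return Measurer(name=prefix, states=states, baselines=(states[0],), role=role)


@pytest.fixture
def abcd_cascade() -> MeasurerCascade:
    """Sensor-reader-interpreter-effector chain of two-state measurers."""
    layers = (
        Layer("A", "sensor", (single_measurer("a", "sensor"),)),
        Layer("B", "reader", (single_measurer("b", "reader"),)),
        Layer("C", "interpreter", (single_measurer("c", "interpreter"),)),
        Layer("D", "effector", (single_measurer("d", "effector"),)),
    )
    couplings = (
        {(("a0",), ("a1",)): ("b1",)},
        {(("b0",), ("b1",)): ("c1",)},
        {(("c0",), ("c1",)): ("d1",)},
    )
    return MeasurerCascade(layers=layers, couplings=couplings)
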