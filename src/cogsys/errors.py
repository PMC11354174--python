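"""Exception hierarchy for cogsys."""


class CogsysError(Exception):
    """Base class for all cogsys errors."""


class ConfigError(CogsysError):
    """A configuration file or in-memory config violates the schema."""


class StateError(CogsysError):
    """A state or joint state is not part of the declared world."""


class CausalViolationError(CogsysError):
    """An attempt to register two successors for one joint state."""


class UndefinedProbabilityError(CogsysError):
    """A conditional ratio has an empty denominator (zero conditioning events).

    Distinct from a ratio of 0: the condition never occurred, so the
    certainty of any event following it is undefined.
    """


class ObserverInfluenceError(CogsysError):
    """A cognizer flagged as an external observer influences the system."""


class BaselineViolationError(CogsysError):
    """An inverse-causality operation was attempted on a sequence that
    departs from an undeclared state."""


class CouplingError(CogsysError):
    """A measurer-cascade coupling has no entry for an observed upstream
    state change."""
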