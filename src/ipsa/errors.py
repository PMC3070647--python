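"""Exception hierarchy for model construction, simulation and analysis."""


class IpsaError(Exception):
    """Base class for all package errors."""


class ConfigError(IpsaError):
    """A model-specification document is malformed or references unknown symbols."""


class ValidationError(IpsaError):
    """Inputs violate a documented precondition (negative Michaelis constant, bad grid...)."""


class GridMismatchError(ValidationError):
    """Two objects that must share a time grid do not."""


class UnknownReactionError(ValidationError):
    """A reaction id does not exist in the model."""

    def __init__(self, reaction_id: str):
        self.reaction_id = reaction_id
        super().__init__(f"unknown reaction id: {reaction_id!r}")


class SimulationError(IpsaError):
    """The ODE integrator failed; carries the time at which it gave up."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        if time is not None:
            message = f"{message} (failure near t={time:g})"
        super().__init__(message)


class NoSwitchError(IpsaError):
    """Trajectory has no detectable switch (derivative ~0 everywhere)."""


class GenerationError(IpsaError):
    """A random fixture could not be stabilised."""
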