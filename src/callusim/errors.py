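"""Exception hierarchy."""


class CallusimError(Exception):
    """Base class for all package errors."""


class GeometryError(CallusimError, ValueError):
    """Invalid geometric specification (sizing, cutter placement, empty fragment)."""


class IntegrityError(CallusimError, RuntimeError):
    """Mesh bookkeeping violated an invariant (duplicate site/node, stale index)."""


class AssemblyError(CallusimError, ValueError):
    """The finite-element system could not be assembled."""


class SolverError(CallusimError, RuntimeError):
    """The linear solver failed to reach the requested residual."""


class ConfigError(CallusimError, ValueError):
    """Configuration file violated the schema; message carries the field path."""


class SimulationError(CallusimError, RuntimeError):
    """The time loop aborted (non-finite concentrations, inconsistent state)."""
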