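"""Exception types shared across the package."""


class CorthickError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CorthickError, ValueError):
    """Invalid parameter or configuration value."""


class ShapeError(CorthickError, ValueError):
    """Mismatched array/table dimensions."""


class DegenerateDataError(CorthickError, ValueError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class ConvergenceError(CorthickError, RuntimeError):
    """Iterative solver failed to reach tolerance."""


class InferenceError(CorthickError, RuntimeError):
    """Bootstrap inference could not be completed reliably."""


class SchemaError(CorthickError, ValueError):
    """A table does not match the expected column schema."""


class JoinError(CorthickError, ValueError):
    """Subject identifiers cannot be matched across tables."""


class ReportError(CorthickError, ValueError):
    """A report cannot be rendered from the given run directory."""
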