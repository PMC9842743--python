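"""Exception hierarchy shared across the package."""


class MolsynapseError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(MolsynapseError, ValueError):
    """A voltage protocol or pulse violates its invariants."""


class TraceParseError(MolsynapseError, ValueError):
    """A trace file could not be parsed; message names the offending line."""


class ConfigurationError(MolsynapseError, ValueError):
    """A solver or pipeline configuration violates its invariants."""


class DomainError(MolsynapseError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SolverError(MolsynapseError, RuntimeError):
    """An iterative solver failed to converge; carries residual history."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class FitFailureError(MolsynapseError, RuntimeError):
    """Nonlinear fitting failed after multi-start; carries best residual."""

    def __init__(self, message, best_residual=None):
        super().__init__(message)
        self.best_residual = best_residual


class ExtractionError(MolsynapseError, ValueError):
    """Per-pulse feature extraction failed; message names the pulse index."""
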