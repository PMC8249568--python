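"""Exception types shared across the package."""


class Sws4dError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(Sws4dError):
    """Raised when input geometry violates a precondition (degenerate points,
    non-positive radii, zero wall thickness, ...)."""


class InfeasibleSpecError(Sws4dError):
    """Raised when a lesion specification cannot be realized geometrically.

    The message names the violated bound.
    """


class ConvergenceError(Sws4dError):
    """Raised when an iterative solve fails; carries the best state seen so far."""

    def __init__(self, message, best=None, trace=None):
        super().__init__(message)
        self.best = best
        self.trace = trace


class ConfigurationError(Sws4dError):
    """Raised for invalid or incomplete run configuration (missing material
    class, unknown config keys, out-of-range values)."""


class SequenceValidationError(Sws4dError):
    """Raised when a cardiac sequence violates its invariants (missing or
    duplicated diastasis frame, inconsistent point counts, non-finite data)."""
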