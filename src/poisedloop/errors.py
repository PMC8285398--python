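"""Exception hierarchy shared by all poisedloop modules."""


class PoisedloopError(Exception):
    """Base class for all package errors."""


class ValidationError(PoisedloopError):
    """Input violates an invariant (coordinates, genome bounds, thresholds)."""


class FormatError(PoisedloopError):
    """A file does not conform to its declared on-disk format."""


class ConfigurationError(PoisedloopError):
    """A pipeline/rule configuration is incomplete or inconsistent."""


class GenerationError(PoisedloopError):
    """A synthetic-data request cannot be satisfied (e.g. infeasible spacing)."""


class ConvergenceError(PoisedloopError):
    """An iterative numerical procedure failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
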