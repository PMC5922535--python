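"""Exception hierarchy for critnet.

All errors raised by the library derive from :class:`CritnetError` so that
callers can catch everything from this package with one clause.
"""


class CritnetError(Exception):
    """Base class for all critnet errors."""


class InvalidArgumentError(CritnetError, ValueError):
    """An argument violates a documented precondition."""


class NumericalFailureError(CritnetError, RuntimeError):
    """A numerical routine (eigensolver, integrator) failed to produce a
    trustworthy result.  Carries optional diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class SingularJacobianError(NumericalFailureError):
    """Newton iteration hit a (numerically) singular Jacobian.

    The offending iterate is attached as ``iterate``.
    """

    def __init__(self, message: str, iterate=None):
        super().__init__(message)
        self.iterate = iterate


class DivergenceError(NumericalFailureError):
    """An iterate became non-finite."""

    def __init__(self, message: str, iterate=None):
        super().__init__(message)
        self.iterate = iterate


class FitUndeterminedError(CritnetError, ValueError):
    """Not enough (or degenerate) data to determine a fit."""


class ConfigError(CritnetError, ValueError):
    """A run configuration failed validation."""
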