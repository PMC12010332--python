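"""Exception hierarchy shared across the package."""


class LinkerThermoError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryFormatError(LinkerThermoError):
    """A trajectory or table file could not be parsed under the named dialect."""


class StructuralError(LinkerThermoError):
    """Input is parseable but structurally inconsistent (e.g. varying atom counts)."""


class SelectionError(LinkerThermoError):
    """A selection query is malformed or refers to an unknown tag."""


class FitError(LinkerThermoError):
    """A least-squares fit is degenerate or otherwise impossible."""


class NumericalError(LinkerThermoError):
    """A numerical precondition failed (e.g. covariance eigenvalue below floor)."""


class SaddlePointError(LinkerThermoError):
    """A Hessian is not at a minimum: imaginary or surplus near-zero modes."""

    def __init__(self, message: str, n_imaginary: int = 0):
        super().__init__(message)
        self.n_imaginary = n_imaginary


class NotAMinimumError(LinkerThermoError):
    """Coordinates handed to a finite-difference Hessian are off-minimum."""


class CapabilityError(LinkerThermoError):
    """The dataset lacks the fields an estimator requires."""


class ConvergenceError(LinkerThermoError):
    """An iterative solver did not reach tolerance within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(LinkerThermoError):
    """A run configuration is malformed (unknown key, bad type, bad value)."""
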