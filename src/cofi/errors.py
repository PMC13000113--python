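"""Exception hierarchy shared across the package."""


class CofiError(Exception):
    """Base class for all package errors."""


class ValidationError(CofiError, ValueError):
    """A parameter or data structure violates its contract."""


class DomainError(CofiError, ValueError):
    """A query falls outside the domain an object is defined on."""


class ConfigurationError(CofiError, ValueError):
    """A configuration is internally inconsistent or unrenderable."""


class ShapeError(CofiError, ValueError):
    """Array shapes are inconsistent between pipeline stages."""


class OverlapError(ValidationError):
    """Temporal windows overlap where they must be disjoint."""


class PluginError(CofiError, RuntimeError):
    """A registered plugin violated its callable contract."""


class NumericalFailureError(CofiError, RuntimeError):
    """An iterative solver produced a non-finite iterate."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class InsufficientDataError(CofiError, ValueError):
    """Too few usable data points for the requested fit."""


class UndefinedCentroidError(CofiError, ValueError):
    """No positive mass remains in the ROI after background subtraction."""


class UndefinedSnrError(CofiError, ValueError):
    """Background mean is non-positive; the intensity ratio is undefined."""
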