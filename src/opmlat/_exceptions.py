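"""Exception hierarchy shared across the package."""


class OpmlatError(Exception):
    """Base class for all package errors."""


class FormatError(OpmlatError):
    """A file does not follow the expected schema (missing column, bad role, ...)."""


class ValidationError(OpmlatError):
    """Input data violates a documented invariant (non-unit orientation, ...)."""


class GeometryError(OpmlatError):
    """Degenerate geometric input (coplanar points, empty grid, ...)."""


class ConfigurationError(OpmlatError):
    """A parameter combination is invalid (window outside epoch, notch above Nyquist, ...)."""


class DomainError(OpmlatError):
    """A physical-model precondition fails (source outside sphere, sensor inside)."""


class ConditioningError(OpmlatError):
    """A matrix is too ill-conditioned to invert without regularization."""


class ContainerError(OpmlatError):
    """An HDF5 container is truncated, corrupt, or of an unsupported schema version."""


class DegenerateError(OpmlatError):
    """A statistic is undefined on this input (zero baseline power/variance)."""
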