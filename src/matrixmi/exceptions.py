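"""Exception hierarchy used across the package."""


class MatrixMIError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MatrixMIError, ValueError):
    """A hyperparameter or option is outside its admissible range."""


class InvalidInputError(MatrixMIError, ValueError):
    """Input data violates a precondition (shape, finiteness, class count)."""


class DegenerateAllocationError(MatrixMIError, ValueError):
    """Window allocation has no defined weights (all variances zero)."""


class ArchiveFormatError(MatrixMIError, ValueError):
    """A trial archive on disk violates the format contract."""


class ConfigurationError(MatrixMIError, ValueError):
    """A pipeline configuration names an unknown method or is inconsistent."""
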