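"""Exception hierarchy for repshape.

Errors are split by contract: file/format problems, per-record problems,
validation of domain objects, bad parameters, and analysis preconditions.
"""


class RepshapeError(Exception):
    """Base class for all repshape errors."""


class FormatError(RepshapeError):
    """A table is structurally unusable (e.g. a mandatory column is missing)."""


class RecordError(RepshapeError):
    """A single input record is invalid (carries a line number when known)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(RepshapeError):
    """A domain object violates one of its invariants."""


class ParameterError(RepshapeError):
    """A model or configuration parameter is outside its valid range."""


class UndefinedFeatureError(RepshapeError):
    """A requested feature is undefined for the given input
    (e.g. insertion statistics when insertion lengths were never recorded)."""


class InsufficientDepthError(RepshapeError):
    """Downsampling depth exceeds the available UMI count."""


class EmptyPartitionError(RepshapeError):
    """A functional/non-functional partition selected no clonotypes."""


class EmptyProfileError(RepshapeError):
    """No clonotype is eligible for the requested profile."""


class ConfigurationError(RepshapeError):
    """Mutually inconsistent arguments (e.g. CDR2 scoring without a library)."""


class InsufficientFeaturesError(RepshapeError):
    """Fewer than two non-constant feature columns remain for multivariate analysis."""


class DegenerateGeometryError(RepshapeError):
    """A distance matrix admits no non-trivial Euclidean embedding."""
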