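"""Exception hierarchy shared across the package."""


class ReefCascadeError(Exception):
    """Base class for all package errors."""


class FormatError(ReefCascadeError):
    """A table is structurally malformed (missing/unknown columns)."""


class ValidationError(ReefCascadeError):
    """Row-level content violates an invariant (negative value, bad label)."""


class ReferenceError_(ReefCascadeError):
    """A record refers to a location absent from the metadata table."""


class ConfigError(ReefCascadeError):
    """A simulation or run configuration is invalid."""


class ConstantSeriesError(ReefCascadeError):
    """A series has zero variance and cannot be standardized."""


class DegenerateDesignError(ReefCascadeError):
    """A regression design matrix is rank deficient or has no spread."""


class InsufficientOverlapError(ReefCascadeError):
    """Two series share fewer than three years."""


class InfiniteZError(ReefCascadeError):
    """|r| = 1: the Fisher transform is infinite."""


class NotApplicableError(ReefCascadeError):
    """A method's applicability condition fails (e.g. uneven site sampling)."""


class IncompleteLocationError(ReefCascadeError):
    """A location is missing one of the three trophic-group results."""


class DegenerateResponseError(ReefCascadeError):
    """A binary response is all zeros or all ones."""
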