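"""Exception hierarchy.

``CohortValidationError`` and ``ConfigurationError`` map to CLI exit code 2
(bad input / bad config); anything else escaping to the CLI maps to exit 1.
"""


class SarocError(Exception):
    """Base class for all saroc errors."""


class CohortValidationError(SarocError):
    """Input data violates an invariant (score out of range, duplicate ids,
    single-class cohort passed to a two-class computation, ...)."""


class ConfigurationError(SarocError):
    """A configuration / column-mapping problem: missing column, malformed
    policy block, unknown preset name."""


class UsageError(SarocError):
    """The API was called incorrectly: wrong number of constraints, foreign
    boundaries, empty grid, enumeration cap exceeded."""


class CalibrationError(SarocError):
    """A distribution-calibration target is unattainable within the family."""


class NumericError(SarocError):
    """A numerical procedure failed to converge or produced no usable value
    (e.g. a statistic undefined on most bootstrap resamples)."""
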