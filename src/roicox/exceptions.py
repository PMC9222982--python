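"""Exception hierarchy shared across the package."""


class RoicoxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RoicoxError, ValueError):
    """Invalid user-supplied configuration (missing columns, bad k, ...)."""


class ParseError(RoicoxError, ValueError):
    """A cell in an input table could not be parsed as a number."""


class ValidationError(RoicoxError, ValueError):
    """Input data violates a structural precondition (e.g. time <= 0)."""


class ShapeError(RoicoxError, ValueError):
    """Dimension mismatch between arrays."""


class EmptyResultError(RoicoxError, ValueError):
    """A filtering step removed every row or every column."""


class UndefinedLikelihoodError(RoicoxError, ValueError):
    """The Cox partial likelihood is undefined (no observed events)."""


class UndefinedMetricError(RoicoxError, ValueError):
    """The concordance index is undefined (no permissible pairs)."""


class DegenerateTestError(RoicoxError, ValueError):
    """A paired test cannot be run (e.g. all differences are zero)."""


class GeneratorError(RoicoxError, RuntimeError):
    """The synthetic-data generator failed to satisfy its constraints."""


class TrainingError(RoicoxError, RuntimeError):
    """Model training diverged (non-finite loss)."""
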