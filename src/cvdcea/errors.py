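"""Exception types shared across the pipeline."""


class CvdceaError(Exception):
    """Base class for package errors."""


class ConfigurationError(CvdceaError):
    """Invalid or infeasible configuration (bad fractions, unknown keys, out-of-range values)."""


class SchemaError(CvdceaError):
    """Input table does not match the required column schema."""


class ValidationError(CvdceaError):
    """Input rows violate invariants (out-of-bounds values, nonpositive weights)."""


class CoefficientError(CvdceaError):
    """A coefficient table is missing a stratum or term."""


class TableRangeError(CvdceaError):
    """A lookup (e.g. age) falls outside the range covered by a table."""
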