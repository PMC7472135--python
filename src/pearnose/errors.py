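"""Exception hierarchy shared across the package."""


class EnoseError(Exception):
    """Base class for all pearnose errors."""


class SchemaError(EnoseError):
    """Structural problem in a table or curve collection (wrong columns,
    inconsistent sensor counts, misaligned rows)."""


class WindowError(EnoseError, ValueError):
    """Stable-value window falls outside the recorded curve duration."""


class DataValidationError(EnoseError):
    """A curve or table contains invalid values (non-finite or non-positive
    conductivity ratios, labels outside the grade range). Names the
    offending sample where possible."""


class CurveParseError(EnoseError):
    """Malformed curve/feature CSV; message carries 1-based line numbers."""


class SamplingError(EnoseError):
    """SMOTE cannot run (too few minority rows, bad neighbour count) or a
    cohort request is empty."""


class ConvergenceError(EnoseError):
    """Training produced a non-finite loss; message carries the epoch."""


class ClusteringError(EnoseError):
    """k-means cannot be run as requested (fewer distinct points than k)."""
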