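"""Exception hierarchy shared across the pipeline stages."""


class EggSyncError(Exception):
    """Base class for all pipeline errors."""


class InvalidMeasurementError(EggSyncError, ValueError):
    """Egg length, width, or volume constant is non-positive."""


class SchemaError(EggSyncError, ValueError):
    """An input table does not match the declared CSV schema."""


class MissingYearError(EggSyncError, ValueError):
    """A year inside the study window has no clutches for a species."""


class SeriesTooShortError(EggSyncError, ValueError):
    """A time series is too short for the requested operation."""


class NonConvergenceError(EggSyncError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class UndefinedSynchronyError(EggSyncError, ValueError):
    """The null entropy is zero (or negative), so phi is undefined."""


class UndefinedCorrelationError(EggSyncError, ValueError):
    """A correlation was requested for a constant series."""


class InsufficientDataError(EggSyncError, ValueError):
    """A data segment is too small for the requested analysis."""
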