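"""Exception types shared across the pipeline stages."""


class ItvOverlapError(Exception):
    """Base class for all package errors."""


class MissingColumnError(ItvOverlapError):
    """A mandatory column is absent from an input table."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        where = f" in {path}" if path else ""
        super().__init__(f"mandatory column {column!r} not found{where}")


class EmptyDatasetError(ItvOverlapError):
    """An input table contains no usable rows."""


class InsufficientSampleError(ItvOverlapError):
    """Fewer trait values than the rarefaction draw size."""


class InsufficientSpeciesError(ItvOverlapError):
    """A community has fewer than two species with usable data."""


class InsufficientDataError(ItvOverlapError):
    """Not enough qualifying observations for a diagnostic."""


class DegenerateDesignError(ItvOverlapError):
    """A regression design with no predictor variance."""


class UndefinedTestError(ItvOverlapError):
    """A paired test whose differences are all zero."""


class ConfigError(ItvOverlapError):
    """Invalid configuration value or unknown configuration key."""
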