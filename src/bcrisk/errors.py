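"""Exception hierarchy.

Errors are grouped by the pipeline exit code they map to: configuration
problems (exit 2), data problems (exit 3) and numerical failures (exit 4).
"""


class BcriskError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(BcriskError):
    """Invalid configuration: bad schema, frequencies not summing to one, ..."""

    exit_code = 2


class DataError(BcriskError):
    """Invalid data: unknown category, empty cohort, missing file, ..."""

    exit_code = 3


class NumericalError(BcriskError):
    """Statistic undefined or estimation failed (separation, zero denominator)."""

    exit_code = 4


class AgeRangeError(DataError):
    """An age falls outside the range covered by an incidence table."""


class PredictionWindowError(DataError):
    """A prediction window is empty (window end at or before window start)."""


class UndefinedStatisticError(NumericalError):
    """A statistic has no defined value for the given input (e.g. O = 0)."""
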