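"""Exception types shared across the pipeline."""


class TopwetError(Exception):
    """Base class for all topwet errors."""


class InvalidConfigError(TopwetError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidParameterError(TopwetError, ValueError):
    """An operation received a parameter outside its valid range."""


class AlignmentError(TopwetError, ValueError):
    """Two series that must share an index/window structure do not."""


class MissingDataError(TopwetError, ValueError):
    """Required observations are absent (e.g. all-NaN)."""


class RangeError(TopwetError, ValueError):
    """A requested window or year lies outside the available data."""


class DegenerateInputError(TopwetError, ValueError):
    """Input has no variance where variance is required (e.g. constant time axis)."""


class UndefinedPercentError(TopwetError, ZeroDivisionError):
    """Percent change requested against a zero base area."""


class ValidationError(TopwetError, ValueError):
    """A data file or in-memory table failed a structural/unit check."""
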