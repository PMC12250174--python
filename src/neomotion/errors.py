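"""Exception hierarchy for neomotion."""


class NeomotionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeomotionError):
    """A landmark file does not follow the expected CSV schema."""


class OrderingError(NeomotionError):
    """Timestamps in a landmark file are not strictly increasing."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class InsufficientDataError(NeomotionError):
    """Too few valid frames for the requested computation."""


class ParameterError(NeomotionError, ValueError):
    """A method parameter is outside its valid range."""


class UnknownRegionError(NeomotionError, KeyError):
    """A body-region name is not in the region table."""


class UnknownMethodError(NeomotionError, KeyError):
    """A motion-quantifier name is not registered."""


class EmptySummaryError(NeomotionError):
    """Windowing produced no usable windows for a summary."""


class ZeroBaselineError(NeomotionError):
    """A ratio or CV was requested against a zero baseline/mean."""
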