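"""Exception hierarchy shared across the package."""


class HhtSannError(Exception):
    """Base class for all package errors."""


class FormatError(HhtSannError):
    """A file could not be parsed; the message names the offending field."""


class UnsupportedDialectError(FormatError):
    """The file is syntactically valid but uses an unsupported variant."""


class ChannelLookupError(HhtSannError, KeyError):
    """A requested channel label does not exist in the recording."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class EmptyInputError(HhtSannError, ValueError):
    """An operation received no usable data (e.g. window longer than signal)."""


class TooShortError(HhtSannError, ValueError):
    """A series is shorter than the minimum length the operation needs."""


class NotEnoughExtremaError(HhtSannError):
    """Envelope construction found fewer than two maxima or minima."""


class ConfigurationError(HhtSannError, ValueError):
    """An unknown method/option identifier was supplied."""


class DimensionError(HhtSannError, ValueError):
    """Array shapes are incompatible with the declared parameters."""


class ProtocolError(HhtSannError, ValueError):
    """A cross-validation protocol precondition is violated."""


class AliasingError(HhtSannError, ValueError):
    """A requested oscillation frequency is at or above Nyquist."""


class PartitionError(HhtSannError, ValueError):
    """A feature-group partition required to be non-empty is empty."""


class UndefinedRatioError(HhtSannError, ZeroDivisionError):
    """The importance-ratio denominator is exactly zero."""


class ConditioningError(HhtSannError):
    """The Shapley regression design matrix is too ill-conditioned to solve."""
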