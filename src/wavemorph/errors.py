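"""Shared exception types."""


class WavemorphError(Exception):
    """Base class for package errors."""


class DomainError(WavemorphError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class InsufficientDataError(WavemorphError, ValueError):
    """Not enough observations to carry out the requested fit or summary."""


class SchemaError(WavemorphError, ValueError):
    """A tabular input does not conform to the expected column schema/ranges."""


class NoIntersectionError(WavemorphError, ValueError):
    """A geometric construction (circle x coastline) has no usable solution."""


class UndefinedMeanError(WavemorphError, ValueError):
    """Circular mean undefined: directions cancel (resultant length ~ 0)."""


class FitFailureError(WavemorphError, RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""
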