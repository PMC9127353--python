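"""Exception hierarchy for the drinkometer pipeline.

Every stage raises a subclass of :class:`DrinkometerError`, so callers (and
the command line) can distinguish validation failures from programming bugs.
"""


class DrinkometerError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DrinkometerError):
    """A file does not follow the documented dialect (missing columns, bad header)."""


class SamplingError(DrinkometerError):
    """A time axis is non-monotone or not uniformly sampled."""


class DataError(DrinkometerError):
    """Signal values are invalid (NaN, non-finite, nonpositive interval)."""


class ChannelError(DrinkometerError):
    """A mapped TDMS channel does not exist in the file."""


class SignalTooShortError(DrinkometerError):
    """The signal is shorter than an operation's minimum length."""


class ConfigError(DrinkometerError):
    """A configuration object violates its invariants."""


class DegenerateFitError(DrinkometerError):
    """Too few or degenerate observations for the requested mixture fit."""


class NoIntersectionError(DrinkometerError):
    """Two mixture components have no density intersection between their means."""


class CriterionUndefinedError(DrinkometerError):
    """A pause criterion cannot be derived (fewer than two components)."""


class EmptyGroupError(DrinkometerError):
    """A survival group contains no events."""


class UndefinedMedianError(DrinkometerError):
    """A survival curve never reaches 50% probability."""


class ComparisonError(DrinkometerError):
    """Fewer than two non-empty groups remain for a survival comparison."""
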