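"""Exception hierarchy for the pcm package.

Every failure mode that callers are expected to handle gets its own class;
all inherit from :class:`PcmError` so ``except PcmError`` catches the lot.
"""


class PcmError(Exception):
    """Base class for all pcm-specific errors."""


class SeriesTooShortError(PcmError, ValueError):
    """A series is too short for the requested delay embedding."""


class DegenerateSeriesError(PcmError, ValueError):
    """A series has (near-)zero variance where variation is required."""


class UndefinedCorrelationError(PcmError, ValueError):
    """A correlation is undefined because one argument has zero variance."""


class SupportError(PcmError, ValueError):
    """Too few overlapping time points to compute a cross map or index."""


class ZeroDenominatorError(PcmError, ZeroDivisionError):
    """Partial correlation denominator vanishes (perfectly collinear pair)."""


class DivergenceError(PcmError, RuntimeError):
    """A simulated trajectory left the admissible state region."""


class CombinatorialBudgetError(PcmError, RuntimeError):
    """A higher-order conditioning request exceeds the configured cap."""


class ParseError(PcmError, ValueError):
    """Malformed delimited-text input (ragged row, missing or bad cell)."""
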