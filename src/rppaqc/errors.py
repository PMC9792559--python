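"""Exception hierarchy for rppaqc.

Every error raised by the package derives from :class:`RppaError`, so callers
can catch the package's failures with a single except clause while still
distinguishing I/O-format problems from scientific-validity problems.
"""


class RppaError(Exception):
    """Base class for all rppaqc errors."""


class FormatError(RppaError):
    """A delimited input file is malformed (e.g. a required column is missing)."""


class ValidationError(RppaError):
    """A value violates a domain invariant (negative intensity, bad class, ...)."""


class PairingError(RppaError):
    """An AP-treated group has no matching untreated group (or vice versa)."""


class DegenerateGroupError(RppaError):
    """A spot group cannot be aggregated (e.g. every spot flagged poor)."""


class DegenerateSignalError(RppaError):
    """An antibody's total signal is zero, so a ratio metric is undefined."""


class DivisionGuardError(RppaError):
    """A background of zero would be divided by; configure a background floor."""


class InsufficientSeriesError(RppaError):
    """Too few distinct dilution points to assess linearity."""


class UnpairedOrDegenerateError(RppaError):
    """No sample has both treatment arms with positive aggregated signal."""


class PanelTooSmallError(RppaError):
    """Fewer than three antibodies: tertile classes are undefined."""


class UndefinedRocError(RppaError):
    """ROC requested with only one class present in the labels."""


class DegenerateTableError(RppaError):
    """A 2x2 contingency table has a zero margin."""


class UndefinedCorrelationError(RppaError):
    """Pearson correlation requested on a zero-variance input."""
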