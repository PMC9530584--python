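"""Exception hierarchy shared across the package.

All public errors derive from :class:`DffgluError` so callers can catch one
base class; the finer-grained subclasses encode the contract each reader or
operation promises (which column is missing, which row failed to parse, which
patient ids failed to join, ...).
"""


class DffgluError(Exception):
    """Base class for all errors raised by dffglu."""


class FormatError(DffgluError):
    """A file is missing a required column or otherwise malformed."""


class ParseError(DffgluError):
    """A cell could not be parsed; carries the offending 1-based row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateSampleError(DffgluError):
    """The same (patient, timestamp) pair appears more than once."""


class JoinError(DffgluError):
    """Cohort metadata rows could not be matched to glucose traces."""

    def __init__(self, message: str, missing_ids: list[str] | None = None):
        super().__init__(message)
        self.missing_ids = missing_ids or []


class InputError(DffgluError, ValueError):
    """An in-memory input violates an operation's precondition."""


class ScaleError(InputError):
    """A requested detrending window length is unusable for the given trace."""


class UndefinedStatisticError(DffgluError):
    """A statistic is mathematically undefined for the given input
    (zero-variance ranking for Spearman, chance agreement of 1 for kappa)."""
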