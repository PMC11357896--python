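"""Exception hierarchy for the singacc pipeline.

All errors derive from :class:`SingaccError` so callers can catch pipeline
failures with a single except clause while still distinguishing data-format
problems from analysis preconditions.
"""


class SingaccError(Exception):
    """Base class for all singacc errors."""


class FormatError(SingaccError):
    """A file or table does not conform to the interchange format.

    Messages name the offending row/column where possible.
    """


class DomainError(SingaccError, ValueError):
    """An argument is outside its mathematical domain (e.g. f0 <= 0)."""


class InsufficientDataError(SingaccError):
    """Too few observations for the statistic; the message names the minimum."""


class AlignmentError(SingaccError):
    """Sung notes cannot be paired with score notes."""


class DesignError(SingaccError):
    """The factorial design is incomplete, unbalanced, or degenerate."""


class NotApplicableError(SingaccError):
    """The measure is undefined for this task (e.g. missed beats without audiation)."""
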