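"""Exception hierarchy for combosearch.

All package-specific errors derive from :class:`ComboSearchError` so callers
can catch everything with one clause; most also derive from the matching
built-in (``ValueError`` / ``RuntimeError``) for idiomatic handling.
"""


class ComboSearchError(Exception):
    """Base class for all combosearch errors."""


class FormatError(ComboSearchError, ValueError):
    """A file does not conform to the expected tabular layout."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class ValidationError(ComboSearchError, ValueError):
    """Input values violate a documented precondition."""


class DegenerateCohortError(ComboSearchError, ValueError):
    """A cohort lacks one of the two outcome classes; AUC is undefined."""


class DegenerateGroupError(ComboSearchError, ValueError):
    """A survival group is empty."""


class DegenerateProbesetError(ValidationError):
    """A probeset has zero variance where positive spread is required."""


class InsufficientDataError(ComboSearchError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(ComboSearchError, ValueError):
    """Rank correlation is undefined (a constant input vector)."""


class PipelineError(ComboSearchError, RuntimeError):
    """A pipeline stage produced an unusable intermediate (e.g. empty filter)."""
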