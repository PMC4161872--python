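"""Exception hierarchy for pbmkit.

All package errors derive from :class:`PBMKitError` so callers can catch one
base class; the subclasses distinguish malformed files, invalid numerical
input, and degenerate data that a computation cannot proceed on.
"""


class PBMKitError(Exception):
    """Base class for all pbmkit errors."""


class FormatError(PBMKitError):
    """A file or table does not conform to the expected layout."""


class DomainError(PBMKitError):
    """An argument violates a precondition (range, length, alphabet)."""


class EmptyInputError(PBMKitError):
    """An operation received no usable data."""


class DegenerateInputError(PBMKitError):
    """Input is valid but carries no information (e.g. zero variance)."""


class CapabilityError(PBMKitError):
    """The input lacks a column/field the requested analysis needs."""


class UndefinedMetricError(PBMKitError):
    """A summary statistic is undefined for this input."""


class FitFailureError(PBMKitError):
    """All optimization restarts diverged; carries the objective traces."""

    def __init__(self, message, traces=None):
        super().__init__(message)
        self.traces = traces or []
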