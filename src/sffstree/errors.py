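"""Exception hierarchy shared by all pipeline stages.

Every error the toolkit raises deliberately derives from :class:`SffstreeError`
so callers (and the CLI) can distinguish declared failure modes from bugs.
"""


class SffstreeError(Exception):
    """Base class for all declared toolkit errors."""


class FormatError(SffstreeError):
    """A file violates its structural contract (markers, duplicate ids, ...)."""


class ParseError(SffstreeError):
    """A cell or row could not be parsed; the message names the location."""


class LabelError(SffstreeError):
    """Sample labels are missing, unknown, or do not cover both classes."""


class AlignmentError(SffstreeError):
    """Objects that must share an identifier universe do not."""


class DomainError(SffstreeError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class InsufficientDataError(SffstreeError):
    """Too few observations for the requested computation."""


class UsageError(SffstreeError):
    """The caller violated an interface precondition."""


class ValidationError(SffstreeError):
    """A domain object failed its invariants at construction time."""


class InputError(SffstreeError):
    """A prediction-time input lacks a required feature value."""
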