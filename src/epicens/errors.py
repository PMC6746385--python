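"""Shared exception types."""


class EpicensError(Exception):
    """Base class for package errors."""


class DataError(EpicensError, ValueError):
    """Invalid, inconsistent or missing input data."""


class FormatError(DataError):
    """A file does not follow the documented schema."""


class InvariantViolation(EpicensError, RuntimeError):
    """An internal physical invariant was violated (e.g. negative storage)."""
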