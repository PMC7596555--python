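"""Exception hierarchy for the pipeline.

All errors derive from :class:`PursuitError` (a ``ValueError``) so callers can
catch pipeline failures with a single except clause while still behaving
sensibly for code that only knows about the standard library.
"""


class PursuitError(ValueError):
    """Base class for all pipeline errors."""


class InvalidParameterError(PursuitError):
    """A parameter violates its documented domain (negative rate, even window...)."""


class EmptySignalError(PursuitError):
    """An operation received a signal with no usable samples."""


class DegenerateSignalError(PursuitError):
    """The signal is formally valid but carries no information (e.g. zero power)."""


class DegenerateGeometryError(PursuitError):
    """Eye geometry is degenerate (e.g. coincident eye corners)."""


class SchemaError(PursuitError):
    """A file does not match the expected column schema or ordering."""
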