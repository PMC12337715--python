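"""Exception hierarchy for eptools.

Every error raised by the library derives from :class:`EPToolsError`, so
callers (and the CLI) can catch one type. Subclasses mirror the failure
modes of the analysis stages: bad parameters, malformed files, values out
of a waveform's span, detection failures, degenerate intervals, and
misaligned measurement vectors.
"""


class EPToolsError(Exception):
    """Base class for all eptools errors."""


class ParameterError(EPToolsError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(EPToolsError, ValueError):
    """A file or stream does not parse as the expected format."""


class RangeError(EPToolsError, ValueError):
    """A time or frequency lies outside the data's span."""


class DetectionError(EPToolsError, RuntimeError):
    """A marking operation found no qualifying feature."""


class DegenerateIntervalError(EPToolsError, ValueError):
    """An interval is too short (or empty) for the requested measure."""


class DegenerateInputError(EPToolsError, ValueError):
    """Input has no variance (or is otherwise statistically degenerate)."""


class AlignmentError(EPToolsError, ValueError):
    """Measurement vectors do not share labels/ordering."""
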