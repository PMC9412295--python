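"""Exception hierarchy for motionval.

All library errors derive from :class:`MotionValError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal bad
inputs rather than internal faults.
"""


class MotionValError(Exception):
    """Base class for all motionval errors."""


class FormatError(MotionValError, ValueError):
    """A file does not match the expected CSV layout (e.g. missing column)."""


class ValidationError(MotionValError, ValueError):
    """A record violates a domain invariant (e.g. end_time <= start_time)."""


class InsufficientDataError(MotionValError, ValueError):
    """Too little data to run an operation (short file, short window)."""


class RangeError(MotionValError, ValueError):
    """A requested time window falls outside the recording span."""


class ParameterError(MotionValError, ValueError):
    """A configuration parameter is out of its admissible range."""


class DegenerateSignalError(MotionValError, ValueError):
    """The signal carries no usable structure (constant input, zero energy)."""


class NoCadenceError(MotionValError, ValueError):
    """No autocorrelation peak qualifies as a step period."""


class UndefinedMeasureError(MotionValError, ValueError):
    """A derived measure is undefined for the given log (e.g. zero steps)."""


class ShapeError(MotionValError, ValueError):
    """Paired arrays have mismatched lengths."""


class IncompleteDesignError(MotionValError, ValueError):
    """An agreement matrix has missing cells."""


class UndefinedICCError(MotionValError, ValueError):
    """The ICC is undefined (zero total variance across all cells)."""


class InsufficientPairsError(MotionValError, ValueError):
    """Too few paired observations for the requested agreement statistic."""
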