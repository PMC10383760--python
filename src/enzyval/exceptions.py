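"""Exception hierarchy for enzyval.

All errors raised by the library derive from :class:`EnzyvalError` so callers
can catch one base class at pipeline boundaries.
"""


class EnzyvalError(Exception):
    """Base class for all enzyval errors."""


class InvalidInputError(EnzyvalError, ValueError):
    """An input value violates a precondition (negative absorbance, wrong role...)."""


class DegenerateCalibrationError(EnzyvalError, ValueError):
    """Standard and blank responses coincide; single-point normalization undefined."""


class InsufficientDataError(EnzyvalError, ValueError):
    """Too few observations / levels for the requested statistic."""


class OutOfRangeError(EnzyvalError, ValueError):
    """A measured concentration falls outside the method's working range."""


class UnresolvedDilutionError(EnzyvalError, RuntimeError):
    """The single automatic dilution pass failed to bring the sample on-scale."""
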