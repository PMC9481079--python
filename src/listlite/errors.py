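"""Exception hierarchy.

Every error a caller can act on derives from :class:`ListliteError`, so the CLI
can map the whole family onto exit code 2 while programmatic users catch the
specific subclass.
"""


class ListliteError(Exception):
    """Base class for all listlite errors."""


class FormatError(ListliteError):
    """A document could not be parsed as the published schema (names line/field)."""


class ValidationError(ListliteError):
    """A parsed document violates a schema invariant (names field and rule)."""


class ScheduleError(ListliteError):
    """An impossible scale-up schedule (e.g. start after end, end past horizon)."""


class DomainError(ListliteError):
    """A numeric argument outside its documented domain (e.g. coverage > 1)."""


class SaturationError(ListliteError):
    """Baseline coverage already removes all amenable deaths for a cause.

    Raised when efficacy x affected_fraction x baseline_coverage >= 1, which
    makes the residual-mortality denominator non-positive.
    """


class DegenerateRiskError(ListliteError):
    """A risk-factor multiplier has a zero denominator (sum p0 * RR == 0)."""


class ConsistencyError(ListliteError):
    """Inputs that must describe the same run do not match."""


class AlignmentError(ListliteError):
    """Two time series share no overlapping years."""
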