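"""Exception hierarchy for mitopet.

All errors raised by the library derive from :class:`MitopetError` so callers
can catch the package's failures with a single except clause.
"""


class MitopetError(Exception):
    """Base class for all mitopet errors."""


class ScheduleError(MitopetError, ValueError):
    """A frame schedule violates its invariants (ordering, overlap, sign)."""


class FormatError(MitopetError, ValueError):
    """An input table or image does not conform to the expected layout."""


class ExtrapolationError(MitopetError, ValueError):
    """An input-function query fell outside the sampled support."""


class FitError(MitopetError, RuntimeError):
    """A kinetic fit could not be performed or did not converge."""


class WindowError(MitopetError, ValueError):
    """A metric window is malformed or not covered by the data."""


class CohortError(MitopetError, ValueError):
    """Cohort statistics preconditions violated (group sizes, variance)."""
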