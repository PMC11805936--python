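"""Exception hierarchy for the dioica pipeline.

Every stage raises a subclass of :class:`DioicaError` so callers can catch
pipeline failures without masking programming errors.
"""


class DioicaError(Exception):
    """Base class for all dioica errors."""


class ParseError(DioicaError):
    """A file could not be parsed; the message names the offending line."""


class DatingError(DioicaError):
    """Ring-width series violate the contiguous-year dating convention."""


class ValidationError(DioicaError):
    """Input values violate a domain invariant."""


class QCError(DioicaError):
    """Quality-control prerequisites (e.g. series overlap) are not met."""


class CoverageError(DioicaError):
    """A requested period is not covered by the available data."""


class DetrendingError(DioicaError):
    """Ratio detrending impossible (fitted line crosses zero)."""


class FitError(DioicaError):
    """A distribution or model fit failed or produced invalid parameters."""


class SelectionError(DioicaError):
    """Model selection cannot proceed (e.g. too few complete cases)."""


class GateError(DioicaError):
    """The log-transform gate was triggered on a nonpositive response."""


class GenerationError(DioicaError):
    """Synthetic-data generation produced out-of-range values."""
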