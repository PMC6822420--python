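"""Exception hierarchy for adaptivent.

All errors raised by the library derive from :class:`AdaptiVentError` so
callers can catch the package's failures with a single except clause.
Precondition violations additionally derive from :class:`ValueError`.
"""


class AdaptiVentError(Exception):
    """Base class for all adaptivent errors."""


class InvalidArgumentError(AdaptiVentError, ValueError):
    """An argument violates a documented precondition."""


class NoSolutionError(AdaptiVentError):
    """No admissible fixed point exists for the requested rate selection."""


class ConvergenceError(AdaptiVentError):
    """An iterative solver failed to converge within its iteration budget."""


class MissingManeuverError(AdaptiVentError):
    """The waveform contains no end-inspiratory occlusion to analyse."""


class InsufficientDataError(AdaptiVentError):
    """Too few samples/breaths/values for the requested computation."""


class InfeasibleParametersError(AdaptiVentError):
    """Cohort parameters cannot produce an eligible patient within the
    rejection-sampling budget."""


class UndefinedCorrelationError(AdaptiVentError):
    """Correlation is undefined because one input has zero variance."""
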