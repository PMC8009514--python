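"""Exception hierarchy for fibrilscatter.

All errors raised by the package derive from :class:`FibrilScatterError`,
so callers (and the pipeline runner) can catch analysis failures without
masking programming errors.
"""


class FibrilScatterError(Exception):
    """Base class for all fibrilscatter errors."""


class ParseError(FibrilScatterError):
    """A data file could not be parsed; the message names the offending line."""


class InsufficientDataError(FibrilScatterError):
    """Too few usable data points for the requested analysis."""


class NotRodlikeError(FibrilScatterError):
    """A rod-Guinier fit found a non-negative slope: the scatterer does not
    show the ln(Iq) vs q^2 decay expected of a long rodlike particle."""


class FitError(FibrilScatterError):
    """A nonlinear fit failed to converge; carries the last parameter state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class OutOfRangeError(FibrilScatterError):
    """A requested inversion target lies outside the attainable range."""


class NumericalError(FibrilScatterError):
    """Quadrature or linear-algebra failure (non-convergence, conditioning)."""
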