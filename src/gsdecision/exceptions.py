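"""Package-specific error types."""


class GSDecisionError(Exception):
    """Base class for all package errors."""


class InvalidPressureError(GSDecisionError, ValueError):
    """Selection pressure outside the open interval (0, 1)."""


class DegenerateTruncationError(GSDecisionError, ValueError):
    """Truncation probability numerically zero; the selected-tail moments are undefined."""


class CovarianceError(GSDecisionError, ValueError):
    """A covariance matrix is not symmetric positive definite (or conformable)."""


class FormatError(GSDecisionError, ValueError):
    """A delimited input file failed validation."""


class SamplerError(GSDecisionError, RuntimeError):
    """An MCMC chain produced non-finite draws."""
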