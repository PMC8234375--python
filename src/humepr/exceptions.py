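"""Exception hierarchy shared across the package."""


class HumeprError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HumeprError, ValueError):
    """A physical parameter is out of its admissible range."""


class DegenerateSpectrumError(HumeprError, ValueError):
    """A spectrum has no usable derivative feature (flat, constant, ...)."""


class ConvergenceError(HumeprError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the last iterate (if any) on the ``last_result`` attribute so
    callers can inspect where the optimizer stalled.
    """

    def __init__(self, message, last_result=None):
        super().__init__(message)
        self.last_result = last_result


class SeriesError(HumeprError, RuntimeError):
    """A power series has too few usable spectra for saturation analysis."""


class ConfigError(HumeprError, ValueError):
    """A generator or run configuration violates its invariants."""


class ParseError(HumeprError, ValueError):
    """A data file could not be parsed; message names the offending line."""
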