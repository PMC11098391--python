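"""Exception types shared across the package."""


class OgttError(Exception):
    """Base class for package-specific errors."""


class DegenerateBoundsError(OgttError, ValueError):
    """Raised when a curve's observed maximum equals its baseline, so the
    amplitude bound interval collapses to a point and the model cannot be fit."""


class UndefinedPeriodError(OgttError, ValueError):
    """Raised for effective_period(0, 0), where the period is undefined."""


class FlatCurveError(OgttError, ValueError):
    """Raised when a predicted curve is constant (A = 0) and has no peak."""


class NonConvergenceError(OgttError, RuntimeError):
    """Raised when the optimizer fails on every restart.

    Carries the best partial state found, if any, in ``best_fit``.
    """

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class DegenerateCohortError(OgttError, ValueError):
    """Raised when a summary column has zero spread and cannot be standardized."""


class SeparationError(OgttError, ValueError):
    """Raised when a logistic model target has a single class."""
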