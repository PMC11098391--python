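"""Ackerman glucose-insulin model: evaluation, box-constrained fitting, analytics.

The model is the closed-form impulse response of a linearized glucose-insulin
system to an oral glucose load,

    Y(t) = Y_F + A * exp(-k t) * sin(omega t),

where ``Y_F`` is fasting glucose (mg/mL), ``A`` sets the excursion amplitude
(mg/mL), ``k`` (1/h) is the exponential damping rate and ``omega`` (1/h) the
oscillation frequency.  The pair (k, omega) combines into the effective
period T_eff = 2*pi / sqrt(k^2 + omega^2), the characteristic recovery time
of the system; values above ~4 h have historically been read as sluggish
glucose regulation.

Fitting is nonlinear least squares over a biologically motivated box:
negative parameters would imply negative fasting glucose, an initial glucose
*drop* after the load, or oscillations growing without bound.  Because the
least-squares surface is multimodal, fitting starts from all-ones (the data
are scaled so optima usually lie in 0-10) and falls back to uniform random
restarts inside the box until a satisfactory fit is found or the start
budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .curves import OGTTCurve
from .errors import DegenerateBoundsError, FlatCurveError, NonConvergenceError, UndefinedPeriodError

__all__ = [
    "AckermanParams",
    "ParameterBounds",
    "AckermanFit",
    "FitConfig",
    "evaluate_model",
    "sse_objective",
    "compute_bounds",
    "effective_period",
    "predicted_maximum",
    "fit_curve",
]


@dataclass(frozen=True)
class AckermanParams:
    """Model parameters: y_F, A in mg/mL; k, omega in 1/hour."""

    y_F: float
    A: float
    k: float
    omega: float

    def as_array(self) -> np.ndarray:
        return np.array([self.y_F, self.A, self.k, self.omega], dtype=float)

    @classmethod
    def from_array(cls, x) -> "AckermanParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for (y_F, A, k, omega); lower is always the zero vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (4,) or upper.shape != (4,):
            raise ValueError("bounds must be 4-vectors")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def contains(self, params: AckermanParams) -> bool:
        x = params.as_array()
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))


@dataclass(frozen=True)
class AckermanFit:
    """Result of fitting one curve: estimates plus fit-quality metadata."""

    params: AckermanParams
    rss: float
    pseudo_r2: float
    t_eff: float
    n_starts_used: int
    converged: bool
    seed: int | None
    bounds: ParameterBounds


@dataclass(frozen=True)
class FitConfig:
    """Controls for the multi-start fitting protocol.

    max_starts is the total budget of initial points (the deterministic
    all-ones start plus uniform draws over the bounds box).  Convergence
    tolerances are set tight so restart coverage, not early stopping,
    governs fit quality.
    """

    max_starts: int = 1000
    seed: int = 0
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    thresholds: object | None = None  # screening.ScreeningThresholds


def evaluate_model(params: AckermanParams, t) -> np.ndarray | float:
    """Model glucose (mg/mL) at time(s) ``t`` in hours."""
    t = np.asarray(t, dtype=float)
    y = params.y_F + params.A * np.exp(-params.k * t) * np.sin(params.omega * t)
    return float(y) if y.ndim == 0 else y


def sse_objective(params: AckermanParams, curve: OGTTCurve) -> float:
    """Sum of squared residuals over the 7 grid points, in (mg/mL)^2."""
    resid = curve.glucose - evaluate_model(params, curve.times)
    return float(resid @ resid)


def compute_bounds(curve: OGTTCurve) -> ParameterBounds:
    """Biological parameter box for one curve.

    y_F in [0, 2*Y(0)], A in [0, 20*(max Y - Y(0))], k in [0, 10],
    omega in [0, 2*pi].  A flat or monotone-decreasing curve collapses the
    amplitude interval and is rejected; such curves should have been
    excluded before fitting.
    """
    y0 = curve.glucose[0]
    peak_excess = float(np.max(curve.glucose) - y0)
    if peak_excess <= 0:
        raise DegenerateBoundsError(
            f"curve {curve.participant_id!r}: observed max equals baseline; "
            "amplitude bound interval is degenerate"
        )
    upper = np.array([2.0 * y0, 20.0 * peak_excess, 10.0, 2.0 * np.pi])
    return ParameterBounds(lower=np.zeros(4), upper=upper)


def effective_period(k: float, omega: float) -> float:
    """Recovery time scale T_eff = 2*pi / sqrt(omega^2 + k^2), in hours."""
    if k == 0.0 and omega == 0.0:
        raise UndefinedPeriodError("effective period undefined for k = omega = 0")
    return 2.0 * np.pi / float(np.hypot(k, omega))


def predicted_maximum(
    params: AckermanParams, horizon: float = 2.0
) -> tuple[float, float, bool]:
    """Global maximum of the predicted curve over [0, inf).

    The stationary points solve tan(omega t) = omega / k; with k > 0 the
    decaying envelope makes the first positive stationary point,
    t = arctan(omega/k) / omega, the global argmax.  With k = 0 the curve is
    an undamped sinusoid peaking at t = pi / (2 omega).  Returns
    (t_max, y_max, during_test) where during_test = (t_max <= horizon);
    the analytic argmax is reported even when it exceeds the horizon.
    """
    if params.A == 0.0:
        raise FlatCurveError("A = 0: predicted curve is flat, no peak")
    if params.omega == 0.0:
        # sin(0*t) == 0 everywhere: constant prediction at fasting level.
        return 0.0, params.y_F, True
    if params.k == 0.0:
        t_max = np.pi / (2.0 * params.omega)
    else:
        t_max = float(np.arctan(params.omega / params.k) / params.omega)
    y_max = float(evaluate_model(params, t_max))
    return t_max, y_max, bool(t_max <= horizon)


def _residuals(x: np.ndarray, times: np.ndarray, glucose: np.ndarray) -> np.ndarray:
    y_f, a, k, w = x
    return glucose - (y_f + a * np.exp(-k * times) * np.sin(w * times))


def _jacobian(x: np.ndarray, times: np.ndarray, glucose: np.ndarray) -> np.ndarray:
    y_f, a, k, w = x
    e = np.exp(-k * times)
    s = np.sin(w * times)
    c = np.cos(w * times)
    jac = np.empty((times.size, 4))
    jac[:, 0] = -1.0
    jac[:, 1] = -e * s
    jac[:, 2] = a * times * e * s
    jac[:, 3] = -a * times * e * c
    return jac


def _pseudo_r2_from_rss(rss: float, glucose: np.ndarray) -> float:
    tss = float(np.sum((glucose - glucose.mean()) ** 2))
    return 1.0 - rss / tss


def fit_curve(
    curve: OGTTCurve,
    bounds: ParameterBounds | None = None,
    config: FitConfig | None = None,
) -> AckermanFit:
    """Fit the model to one curve with the multi-start protocol.

    Runs box-constrained least squares from the all-ones start; if the
    converged fit would be classified inadequate by the screening module,
    restarts from uniform draws over the bounds box, up to
    ``config.max_starts`` starts in total.  Returns the first satisfactory
    fit found, else the minimum-RSS converged fit across all starts (ties
    broken by earliest start).
    """
    from . import screening  # local import: screening depends on this module

    if config is None:
        config = FitConfig()
    if bounds is None:
        bounds = compute_bounds(curve)
    thresholds = config.thresholds or screening.ScreeningThresholds()

    times, glucose = curve.times, curve.glucose
    rng = np.random.default_rng(config.seed)
    best: AckermanFit | None = None
    x0 = np.clip(np.ones(4), bounds.lower, bounds.upper)

    for start_idx in range(config.max_starts):
        if start_idx > 0:
            x0 = rng.uniform(bounds.lower, bounds.upper)
        try:
            res = least_squares(
                _residuals,
                x0,
                jac=_jacobian,
                bounds=(bounds.lower, bounds.upper),
                args=(times, glucose),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                gtol=config.gtol,
            )
        except Exception:
            continue
        if not res.success:
            continue
        params = AckermanParams.from_array(res.x)
        rss = float(2.0 * res.cost)
        fit = AckermanFit(
            params=params,
            rss=rss,
            pseudo_r2=_pseudo_r2_from_rss(rss, glucose),
            t_eff=effective_period(params.k, params.omega),
            n_starts_used=start_idx + 1,
            converged=True,
            seed=config.seed,
            bounds=bounds,
        )
        if best is None or fit.rss < best.rss:
            best = fit
        if screening.classify(fit, curve, bounds, thresholds).adequate:
            return fit
    if best is None:
        raise NonConvergenceError(
            f"optimizer failed on all {config.max_starts} starts "
            f"for curve {curve.participant_id!r}",
            best_fit=None,
        )
    return replace(best, n_starts_used=config.max_starts)
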