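"""Fit-adequacy screening for Ackerman model fits.

In a heterogeneous cohort many curves are not well described by a damped
sinusoid, and the least-squares fit fails in recognizable ways.  Three
non-exclusive patterns mark a fit inadequate:

* **boundary fits** — one or more estimates land on the edge of the
  biological parameter box, typically a symptom of practical
  non-identifiability (a nearly flat likelihood near the optimum);
* **extrapolated fits** — the predicted peak glucose, when it occurs within
  the 2 h test window, misses the observed peak by at least ``delta_tol``
  in relative terms (the absolute value matters: severe *under*-prediction
  is just as disqualifying as over-prediction);
* **low pseudo-R²** — the fit barely improves on an intercept-only model
  (cutoff 0.7).

A fit is adequate iff none of the three flags is set.  Separately, curves
whose 20-minute glucose is strictly below baseline are excluded before any
fitting: an initial decline after a glucose load is physiologically
anomalous and outside the model's reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ackerman import AckermanFit, ParameterBounds, predicted_maximum
from .curves import OGTTCurve
from .errors import FlatCurveError

__all__ = [
    "ScreeningThresholds",
    "FitClassification",
    "exclude_pre_fit",
    "pseudo_r2",
    "is_boundary_fit",
    "is_extrapolated_fit",
    "classify",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """Cutoffs for the three inadequacy criteria.

    delta_tol: allowed relative discrepancy between predicted and observed
    peak glucose (default 10%).  r2_cutoff: minimum pseudo-R² (default 0.7).
    boundary_rel_tol: an estimate within this fraction of the bound-interval
    width of either end counts as "on the boundary" (default 1e-4).
    """

    delta_tol: float = 0.10
    r2_cutoff: float = 0.7
    boundary_rel_tol: float = 1e-4

    def __post_init__(self):
        if self.delta_tol <= 0:
            raise ValueError("delta_tol must be positive")
        if not 0 < self.r2_cutoff < 1:
            raise ValueError("r2_cutoff must lie in (0, 1)")
        if self.boundary_rel_tol <= 0:
            raise ValueError("boundary_rel_tol must be positive")


@dataclass(frozen=True)
class FitClassification:
    """Per-fit screening verdict; the three flags are non-exclusive."""

    excluded_pre_fit: bool
    boundary: bool
    extrapolated: bool
    low_r2: bool
    adequate: bool


def exclude_pre_fit(curve: OGTTCurve) -> bool:
    """True iff glucose at 20 min is strictly below the baseline draw."""
    return bool(curve.glucose[1] < curve.glucose[0])


def pseudo_r2(observed, predicted) -> float:
    """1 - RSS / TSS against the observed mean; undefined for constant data."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    tss = float(np.sum((observed - observed.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("pseudo-R2 undefined: observations are constant")
    rss = float(np.sum((observed - predicted) ** 2))
    return 1.0 - rss / tss


def is_boundary_fit(
    fit: AckermanFit,
    bounds: ParameterBounds,
    thresholds: ScreeningThresholds | None = None,
) -> bool:
    """True iff any estimate lies within ``boundary_rel_tol`` of the box edge,
    measured as a fraction of each parameter's interval width."""
    thresholds = thresholds or ScreeningThresholds()
    width = bounds.upper - bounds.lower
    if np.any(width <= 0):
        raise ValueError("degenerate bounds: zero-width parameter interval")
    x = fit.params.as_array()
    tol = thresholds.boundary_rel_tol * width
    return bool(np.any(x - bounds.lower <= tol) or np.any(bounds.upper - x <= tol))


def is_extrapolated_fit(
    fit: AckermanFit,
    curve: OGTTCurve,
    thresholds: ScreeningThresholds | None = None,
) -> bool:
    """True iff the predicted peak occurs within the test window and misses
    the observed peak by at least delta_tol in relative terms.

    The during-test condition keeps well-fitting but slow-peaking curves
    (argmax after 2 h) from being flagged.
    """
    thresholds = thresholds or ScreeningThresholds()
    try:
        _, y_max_pred, during_test = predicted_maximum(fit.params, horizon=curve.times[-1])
    except FlatCurveError:
        # A-hat = 0: constant prediction at fasting level, peak is at t=0.
        y_max_pred, during_test = fit.params.y_F, True
    if not during_test:
        return False
    y_max_obs = float(np.max(curve.glucose))
    return bool(abs(y_max_pred - y_max_obs) / y_max_obs >= thresholds.delta_tol)


def classify(
    fit: AckermanFit,
    curve: OGTTCurve,
    bounds: ParameterBounds,
    thresholds: ScreeningThresholds | None = None,
) -> FitClassification:
    """Apply all three criteria; adequate iff none fires.

    The caller is expected to have applied :func:`exclude_pre_fit` already;
    the returned record carries that flag for bookkeeping.
    """
    thresholds = thresholds or ScreeningThresholds()
    boundary = is_boundary_fit(fit, bounds, thresholds)
    extrapolated = is_extrapolated_fit(fit, curve, thresholds)
    low_r2 = bool(fit.pseudo_r2 < thresholds.r2_cutoff)
    return FitClassification(
        excluded_pre_fit=exclude_pre_fit(curve),
        boundary=boundary,
        extrapolated=extrapolated,
        low_r2=low_r2,
        adequate=not (boundary or extrapolated or low_r2),
    )
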