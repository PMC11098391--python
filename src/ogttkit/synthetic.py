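"""Synthetic OGTT cohort generator.

The reference cohort for this methodology (community-dwelling adults aged
50+ with 7-draw OGTTs, gait speed and mortality follow-up) is not publicly
available, so every downstream stage is exercised on simulated data with
the same statistical structure:

* typical curves follow the damped-sinusoid glucose model with parameters
  drawn uniformly from ranges chosen so the population mean curve lands
  near the reported landmarks (fasting ~97 mg/dL, peak ~161 mg/dL near
  49 min, 2 h ~130 mg/dL), plus homoscedastic mean-zero Gaussian noise;
* a configurable fraction of curves take atypical shapes (biphasic,
  continuous rise, oscillating, early drop) built piecewise, since such
  curves exist in real cohorts but have no parametric generative model —
  these give the fit-adequacy screen something to catch;
* gait speed is linear in demographics and a curve-derived latent feature
  (an early-peak/late-clearance contrast standing in for the second fPC),
  survival is exponential with a log-hazard linear in the same terms and
  administrative censoring, and all true coefficients are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ackerman import AckermanParams, evaluate_model
from .curves import OGTTCurve, TIME_GRID_HOURS
from .stage_two import CohortRecord

__all__ = [
    "ParamRanges",
    "OutcomeCoefficients",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_ackerman_curve",
    "simulate_atypical_curve",
    "simulate_cohort",
    "ATYPICAL_SHAPES",
]

ATYPICAL_SHAPES = ("biphasic", "continuous_rise", "oscillating", "early_drop")

_RACE_LEVELS = np.array(["White", "Black", "NonWhiteNonBlack"])


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges for typical-curve parameters (mg/mL, 1/h).

    All ranges lie strictly inside the fitting box so zero-noise typical
    curves are recoverable as interior optima.
    """

    y_F: tuple[float, float] = (0.75, 1.25)
    A: tuple[float, float] = (0.3, 2.0)
    k: tuple[float, float] = (0.5, 3.0)
    omega: tuple[float, float] = (1.0, 4.5)


@dataclass(frozen=True)
class OutcomeCoefficients:
    """True generative coefficients for the outcome models.

    Gait speed (m/s): intercept + effects of the standardized latent curve
    feature, age (per 10 y above 70), BMI (per 5 units above 27) and male
    sex, plus Gaussian noise.  Survival: exponential with baseline rate
    (events/year) and log-hazard linear in the same terms; the default
    latent log-hazard corresponds to HR 0.80 per SD.
    """

    gait_intercept: float = 1.05
    gait_latent: float = 0.02
    gait_age10: float = -0.05
    gait_bmi5: float = -0.02
    gait_male: float = 0.05
    gait_noise_sd: float = 0.15
    hazard_baseline_rate: float = 0.035
    loghr_latent: float = float(np.log(0.80))
    loghr_age10: float = float(np.log(1.5))
    loghr_bmi5: float = 0.05
    loghr_male: float = 0.30


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 1000
    fraction_atypical: float = 0.25
    noise_sd: float = 0.05  # glucose mg/mL (5 mg/dL), homoscedastic
    param_ranges: ParamRanges = field(default_factory=ParamRanges)
    outcome_coefficients: OutcomeCoefficients = field(default_factory=OutcomeCoefficients)
    censoring_time: float = 15.0  # years of administrative follow-up
    missing_smoking_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.fraction_atypical <= 1.0:
            raise ValueError("fraction_atypical must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.censoring_time < 0:
            raise ValueError("censoring_time must be non-negative")


@dataclass(frozen=True)
class SyntheticCohort:
    """Curves, covariate/outcome records and full generative truth."""

    curves: list[OGTTCurve]
    records: list[CohortRecord]
    truth: pd.DataFrame  # per-participant true params, shape, latent feature
    config: SimulationConfig


def simulate_ackerman_curve(
    params: AckermanParams,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
) -> OGTTCurve:
    """Model curve on the 7-point grid plus iid Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if min(params.y_F, params.A, params.k, params.omega) < 0:
        raise ValueError("parameters must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = evaluate_model(params, TIME_GRID_HOURS)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=7)
    return OGTTCurve(participant_id, y)


def _biphasic(rng: np.random.Generator) -> np.ndarray:
    """Two interior local maxima (at 40 and 80 min)."""
    g0 = rng.uniform(0.85, 1.05)
    y1 = g0 + rng.uniform(0.15, 0.30)
    y2 = y1 + rng.uniform(0.10, 0.25)  # first peak
    y3 = y2 - rng.uniform(0.10, 0.20)
    y4 = y3 + rng.uniform(0.05, min(0.15, y2 - y3 - 0.02))  # second peak below first
    y5 = y4 - rng.uniform(0.05, 0.15)
    y6 = y5 - rng.uniform(0.03, 0.10)
    return np.array([g0, y1, y2, y3, y4, y5, y6])


def _continuous_rise(rng: np.random.Generator) -> np.ndarray:
    g0 = rng.uniform(0.85, 1.05)
    return g0 + np.concatenate([[0.0], np.cumsum(rng.uniform(0.05, 0.25, size=6))])


def _oscillating(rng: np.random.Generator) -> np.ndarray:
    """Alternating rises and falls of at least 0.2 mg/mL (20 mg/dL)."""
    y = [rng.uniform(0.90, 1.00)]
    sign = 1.0
    for _ in range(6):
        y.append(y[-1] + sign * rng.uniform(0.20, 0.35))
        sign = -sign
    return np.array(y)


def _early_drop(rng: np.random.Generator) -> np.ndarray:
    """20-minute glucose strictly below baseline; triggers pre-fit exclusion."""
    g0 = rng.uniform(0.90, 1.10)
    y1 = g0 - rng.uniform(0.05, 0.15)
    y2 = y1 + rng.uniform(0.20, 0.40)
    y3 = y2 + rng.uniform(0.05, 0.15)
    y4 = y3 - rng.uniform(0.02, 0.10)
    y5 = y4 - rng.uniform(0.02, 0.10)
    y6 = y5 - rng.uniform(0.02, 0.10)
    return np.array([g0, y1, y2, y3, y4, y5, y6])


_SHAPE_BUILDERS = {
    "biphasic": _biphasic,
    "continuous_rise": _continuous_rise,
    "oscillating": _oscillating,
    "early_drop": _early_drop,
}


def simulate_atypical_curve(
    shape: str,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
) -> OGTTCurve:
    """One atypical curve of the named shape, built piecewise (not from the
    damped-sinusoid model)."""
    if shape not in _SHAPE_BUILDERS:
        raise ValueError(f"unknown atypical shape {shape!r}; choose from {ATYPICAL_SHAPES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return OGTTCurve(participant_id, _SHAPE_BUILDERS[shape](rng))


def _latent_feature(glucose: np.ndarray) -> np.ndarray:
    """Early-peak/late-clearance contrast: mean glucose at 20-60 min minus
    mean at 80-120 min, per curve.  Positive values mirror the second fPC's
    'early rise, fast clearance' mode."""
    return glucose[:, 1:4].mean(axis=1) - glucose[:, 4:7].mean(axis=1)


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort: curves, demographics, outcomes, truth.

    Deterministic given the config (including its seed).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i:05d}" for i in range(n)]

    atypical = rng.random(n) < config.fraction_atypical
    shapes = rng.choice(ATYPICAL_SHAPES, size=n)
    pr = config.param_ranges
    params = np.column_stack(
        [
            rng.uniform(*pr.y_F, size=n),
            rng.uniform(*pr.A, size=n),
            rng.uniform(*pr.k, size=n),
            rng.uniform(*pr.omega, size=n),
        ]
    )
    noise = rng.normal(0.0, config.noise_sd, size=(n, 7)) if config.noise_sd > 0 else np.zeros((n, 7))

    t = TIME_GRID_HOURS
    model_vals = params[:, [0]] + params[:, [1]] * np.exp(-params[:, [2]] * t) * np.sin(
        params[:, [3]] * t
    )
    glucose = model_vals + noise
    for i in np.flatnonzero(atypical):
        glucose[i] = _SHAPE_BUILDERS[shapes[i]](rng)
    glucose = np.maximum(glucose, 0.05)  # guard against noise driving values <= 0

    curves = [OGTTCurve(pid, g) for pid, g in zip(ids, glucose)]

    # Demographics.
    age = rng.uniform(50.0, 95.0, size=n)
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 16.0, 45.0)
    male = rng.random(n) < 0.48
    race = rng.choice(_RACE_LEVELS, size=n, p=[0.65, 0.25, 0.10])
    smoker = rng.random(n) < 0.40
    smoking_missing = rng.random(n) < config.missing_smoking_fraction

    # Latent curve feature, standardized within the cohort.
    raw_latent = _latent_feature(glucose)
    sd = raw_latent.std(ddof=1) if n > 1 else 1.0
    latent = (raw_latent - raw_latent.mean()) / sd if sd > 0 else np.zeros(n)

    oc = config.outcome_coefficients
    lin = (
        oc.gait_latent * latent
        + oc.gait_age10 * (age - 70.0) / 10.0
        + oc.gait_bmi5 * (bmi - 27.0) / 5.0
        + oc.gait_male * male
    )
    gait = oc.gait_intercept + lin + rng.normal(0.0, oc.gait_noise_sd, size=n)
    gait = np.maximum(gait, 0.1)

    log_hazard = (
        oc.loghr_latent * latent
        + oc.loghr_age10 * (age - 70.0) / 10.0
        + oc.loghr_bmi5 * (bmi - 27.0) / 5.0
        + oc.loghr_male * male
    )
    rate = oc.hazard_baseline_rate * np.exp(log_hazard)
    death_time = rng.exponential(1.0 / rate)
    survival_time = np.minimum(death_time, config.censoring_time)
    event = (death_time <= config.censoring_time).astype(int)

    records = [
        CohortRecord(
            participant_id=ids[i],
            age=float(age[i]),
            bmi=float(bmi[i]),
            sex="male" if male[i] else "female",
            race=str(race[i]),
            smoking=None if smoking_missing[i] else ("ever" if smoker[i] else "never"),
            gait_speed=float(gait[i]),
            survival_time=float(survival_time[i]),
            event=int(event[i]),
        )
        for i in range(n)
    ]

    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "atypical": atypical,
            "shape": np.where(atypical, shapes, "typical"),
            "y_F": np.where(atypical, np.nan, params[:, 0]),
            "A": np.where(atypical, np.nan, params[:, 1]),
            "k": np.where(atypical, np.nan, params[:, 2]),
            "omega": np.where(atypical, np.nan, params[:, 3]),
            "latent": latent,
            "death_time": death_time,
        }
    )
    return SyntheticCohort(curves=curves, records=records, truth=truth, config=config)
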