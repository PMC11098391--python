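"""Stage-two and auxiliary regressions linking curve summaries to outcomes.

The two-stage design first reduces each OGTT curve to a handful of
summaries (Ackerman parameter estimates and effective period; fPC scores)
and then regresses outcomes on those summaries.  Ackerman summaries are
standardized against the adequate-fit subcohort and gated: for inadequate
fits every Ackerman column (and the adequate-fit indicator) is exactly
zero, which is equivalent to giving inadequate fits a separate intercept
and estimating the parameter effects on adequate fits only.  fPC scores
are mean-zero by construction, so they are scaled by the cohort standard
deviation without centering.

Gait-speed models use ordinary least squares with a cubic B-spline in age
(knots 65/75/85); survival models are Cox proportional hazards with a
linear age term (Efron tie handling).  Auxiliary models relate summaries
to demographics: a logistic model for the odds of an inadequate fit, a
linear model for effective period among adequate fits, and linear models
for each fPC score.  Reference coding: female sex, Black race,
never-smoker.  Age enters auxiliary/stage-two covariates per 10 years and
BMI per 5 units.  Records with missing smoking history are dropped here
(they still contribute to stage one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.interpolate import BSpline

from .errors import DegenerateCohortError, SeparationError

__all__ = [
    "CohortRecord",
    "records_to_frame",
    "frame_to_records",
    "standardize_summaries",
    "standardize_table",
    "age_spline_basis",
    "build_gait_design",
    "fit_gait_models",
    "fit_cox_models",
    "fit_auxiliary_models",
    "GAIT_MODEL_COLUMNS",
]

RACE_LEVELS = ("White", "Black", "NonWhiteNonBlack")

#: Summary columns (beyond demographics) for each gait-speed model.
GAIT_MODEL_COLUMNS = {
    "1": ["adequate_indicator", "log_yF_std", "k_std", "omega_std"],
    "2": ["adequate_indicator", "teff_std"],
    "3": ["adequate_indicator", "teff_std", "log_yF_std"],
    "4": ["adequate_indicator", "teff_std", "log_yF_std", "k_std"],
    "fpc": ["pc1_std", "pc2_std", "pc3_std"],
}

_ACKERMAN_STD_COLS = ["log_yF_std", "log_A_std", "k_std", "omega_std", "teff_std"]
_PC_STD_COLS = ["pc1_std", "pc2_std", "pc3_std"]


@dataclass(frozen=True)
class CohortRecord:
    """Demographics and outcomes for one participant."""

    participant_id: str
    age: float  # years, >= 50
    bmi: float  # kg/m^2
    sex: str  # "male" / "female"
    race: str  # White / Black / NonWhiteNonBlack
    smoking: Optional[str]  # "ever" / "never" / None (missing)
    gait_speed: float  # m/s, faster of two 6 m walks
    survival_time: float  # years
    event: int  # 1 = death observed

    def __post_init__(self):
        if self.age < 50:
            raise ValueError("cohort restricted to ages 50 and older")
        if self.gait_speed <= 0:
            raise ValueError("gait speed must be positive")
        if self.survival_time < 0:
            raise ValueError("survival time must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.race not in RACE_LEVELS:
            raise ValueError(f"unknown race {self.race!r}")
        if self.smoking is not None and self.smoking not in ("ever", "never"):
            raise ValueError(f"unknown smoking level {self.smoking!r}")


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def frame_to_records(frame: pd.DataFrame) -> list[CohortRecord]:
    out = []
    for _, row in frame.iterrows():
        smoking = row["smoking"]
        if pd.isna(smoking):
            smoking = None
        out.append(
            CohortRecord(
                participant_id=str(row["participant_id"]),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                sex=str(row["sex"]),
                race=str(row["race"]),
                smoking=smoking,
                gait_speed=float(row["gait_speed"]),
                survival_time=float(row["survival_time"]),
                event=int(row["event"]),
            )
        )
    return out


def standardize_table(table: pd.DataFrame, adequate: pd.Series) -> pd.DataFrame:
    """Center/scale Ackerman columns on adequate-fit statistics and zero them
    for inadequate fits; scale PC columns by the cohort SD without centering.

    ``table`` must already hold the log-transformed Ackerman columns.  This
    step is idempotent: applying it to its own output is a no-op.
    """
    out = table.copy()
    adequate = adequate.astype(bool).to_numpy()
    if not adequate.any():
        raise DegenerateCohortError("no adequate fits to standardize against")
    for col in _ACKERMAN_STD_COLS:
        vals = out[col].to_numpy(dtype=float)
        mu = vals[adequate].mean()
        sd = vals[adequate].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateCohortError(f"zero spread in column {col!r} among adequate fits")
        out[col] = np.where(adequate, (vals - mu) / sd, 0.0)
    for col in _PC_STD_COLS:
        vals = out[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateCohortError(f"zero spread in column {col!r}")
        out[col] = vals / sd
    out["adequate_indicator"] = adequate.astype(float)
    return out


def standardize_summaries(
    fits: pd.DataFrame, classifications: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the standardized stage-two summary table.

    ``fits`` needs columns participant_id, y_F, A, k, omega, t_eff;
    ``classifications`` needs participant_id and adequate; ``scores`` needs
    participant_id and pc1..pc3.  y_F and A are log-transformed (their raw
    distributions are right-skewed).  Returns one row per participant with
    the standardized columns, the adequate indicator, and raw effective
    period in hours (``teff_hours``, NaN for inadequate fits) kept for the
    auxiliary models.
    """
    merged = (
        fits.merge(classifications[["participant_id", "adequate"]], on="participant_id")
        .merge(
            scores.rename(columns={"pc1": "pc1_std", "pc2": "pc2_std", "pc3": "pc3_std"}),
            on="participant_id",
        )
        .reset_index(drop=True)
    )
    if len(merged) != len(fits):
        raise ValueError("participant sets of fits, classifications and scores differ")
    if np.any(merged[["y_F", "A"]].to_numpy() <= 0):
        raise ValueError("y_F and A must be positive to log-transform")
    table = pd.DataFrame(
        {
            "participant_id": merged["participant_id"],
            "log_yF_std": np.log(merged["y_F"].to_numpy(dtype=float)),
            "log_A_std": np.log(merged["A"].to_numpy(dtype=float)),
            "k_std": merged["k"].astype(float),
            "omega_std": merged["omega"].astype(float),
            "teff_std": merged["t_eff"].astype(float),
            "pc1_std": merged["pc1_std"].astype(float),
            "pc2_std": merged["pc2_std"].astype(float),
            "pc3_std": merged["pc3_std"].astype(float),
        }
    )
    out = standardize_table(table, merged["adequate"])
    out["teff_hours"] = np.where(
        merged["adequate"].astype(bool), merged["t_eff"].astype(float), np.nan
    )
    return out


def age_spline_basis(age: np.ndarray, boundary: tuple[float, float] | None = None) -> pd.DataFrame:
    """Cubic B-spline basis in age with interior knots at 65, 75, 85 years.

    Boundary knots default to the cohort age range.  The first basis column
    is dropped so the basis can coexist with a model intercept.
    """
    age = np.asarray(age, dtype=float)
    if boundary is None:
        boundary = (float(age.min()), float(age.max()))
    lo, hi = boundary
    interior = [k for k in (65.0, 75.0, 85.0) if lo < k < hi]
    knots = np.concatenate([np.full(4, lo), interior, np.full(4, hi)])
    basis = BSpline.design_matrix(np.clip(age, lo, hi), knots, 3).toarray()
    cols = {f"age_spline_{j}": basis[:, j] for j in range(1, basis.shape[1])}
    return pd.DataFrame(cols, index=pd.RangeIndex(len(age)))


def _demographic_design(records: pd.DataFrame, age_spline: bool) -> pd.DataFrame:
    design = pd.DataFrame(index=pd.RangeIndex(len(records)))
    design["intercept"] = 1.0
    age = records["age"].to_numpy(dtype=float)
    if age_spline:
        design = pd.concat([design, age_spline_basis(age)], axis=1)
    else:
        design["age_10yr"] = age / 10.0
    design["bmi_5unit"] = records["bmi"].to_numpy(dtype=float) / 5.0
    design["sex_male"] = (records["sex"] == "male").astype(float).to_numpy()
    design["race_White"] = (records["race"] == "White").astype(float).to_numpy()
    design["race_NonWhiteNonBlack"] = (
        (records["race"] == "NonWhiteNonBlack").astype(float).to_numpy()
    )
    design["smoking_ever"] = (records["smoking"] == "ever").astype(float).to_numpy()
    return design


def _drop_missing_smoking(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["smoking"].notna()].reset_index(drop=True)


def build_gait_design(
    records: pd.DataFrame, summaries: pd.DataFrame, model_id: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and outcome vector for one gait-speed model.

    model_id in {"1", "2", "3", "4", "fpc"}.  Returns (design, gait_speed)
    after dropping records with missing smoking history.
    """
    model_id = str(model_id)
    if model_id not in GAIT_MODEL_COLUMNS:
        raise ValueError(f"unknown gait model {model_id!r}")
    merged = _drop_missing_smoking(records.merge(summaries, on="participant_id"))
    design = _demographic_design(merged, age_spline=True)
    for col in GAIT_MODEL_COLUMNS[model_id]:
        design[col] = merged[col].to_numpy(dtype=float)
    return design, merged["gait_speed"].astype(float)


def _coef_table(params, bse, ci, pvalues) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": pvalues,
        }
    )


def fit_gait_models(design: pd.DataFrame, gait_speed: pd.Series) -> pd.DataFrame:
    """OLS fit with Wald 95% intervals; raises on a rank-deficient design."""
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear columns)")
    res = sm.OLS(np.asarray(gait_speed, dtype=float), X).fit()
    ci = res.conf_int()
    table = _coef_table(res.params, res.bse, (ci[:, 0], ci[:, 1]), res.pvalues)
    table.index = design.columns
    return table


def fit_cox_models(
    records: pd.DataFrame, summaries: pd.DataFrame, model_spec: str = "ackerman"
) -> pd.DataFrame:
    """Cox proportional-hazards model of death (Efron ties via lifelines).

    model_spec "ackerman" uses the adequate-fit indicator and gated
    effective period; "fpc" uses the three standardized PC scores.  All
    models adjust for linear age (per 10 years), BMI (per 5), sex, race and
    smoking.  Returns a table with log-HR, HR, CI and p-values.
    """
    if model_spec == "ackerman":
        cols = ["adequate_indicator", "teff_std"]
    elif model_spec == "fpc":
        cols = ["pc1_std", "pc2_std", "pc3_std"]
    else:
        raise ValueError(f"unknown Cox model spec {model_spec!r}")
    merged = _drop_missing_smoking(records.merge(summaries, on="participant_id"))
    if int(merged["event"].sum()) == 0:
        raise ValueError("degenerate partial likelihood: no events observed")
    design = _demographic_design(merged, age_spline=False).drop(columns=["intercept"])
    for col in cols:
        design[col] = merged[col].to_numpy(dtype=float)
    df = design.copy()
    df["survival_time"] = merged["survival_time"].to_numpy(dtype=float)
    df["event"] = merged["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="survival_time", event_col="event")
    summary = cph.summary
    table = pd.DataFrame(
        {
            "coef": summary["coef"],
            "se": summary["se(coef)"],
            "hr": summary["exp(coef)"],
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p_value": summary["p"],
        }
    )
    return table


def _fit_logit(design: pd.DataFrame, target: np.ndarray) -> pd.DataFrame:
    if len(np.unique(target)) < 2:
        raise SeparationError("logistic target has a single class")
    res = sm.Logit(target, design.to_numpy(dtype=float)).fit(disp=False)
    ci = res.conf_int()
    table = _coef_table(res.params, res.bse, (ci[:, 0], ci[:, 1]), res.pvalues)
    table.index = design.columns
    table["odds_ratio"] = np.exp(table["coef"])
    return table


def fit_auxiliary_models(
    records: pd.DataFrame,
    summaries: pd.DataFrame,
    classifications: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Models relating stage-one summaries to personal characteristics.

    Returns tables keyed: "inadequate_logistic" (odds of an inadequate fit
    on demographics), "teff_linear" (effective period in hours on
    demographics, adequate fits only), "pc{1,2,3}_linear" (standardized
    scores on demographics), and "inadequate_on_pcs" (odds of an inadequate
    fit on the three PC scores).
    """
    merged = _drop_missing_smoking(
        records.merge(summaries, on="participant_id").merge(
            classifications[["participant_id", "adequate"]], on="participant_id"
        )
    )
    inadequate = (~merged["adequate"].astype(bool)).to_numpy(dtype=float)
    demo = _demographic_design(merged, age_spline=False)

    out: dict[str, pd.DataFrame] = {}
    out["inadequate_logistic"] = _fit_logit(demo, inadequate)

    adequate_rows = merged["adequate"].astype(bool).to_numpy()
    demo_adequate = demo[adequate_rows]
    teff = merged.loc[adequate_rows, "teff_hours"].to_numpy(dtype=float)
    res = sm.OLS(teff, demo_adequate.to_numpy(dtype=float)).fit()
    ci = res.conf_int()
    table = _coef_table(res.params, res.bse, (ci[:, 0], ci[:, 1]), res.pvalues)
    table.index = demo.columns
    out["teff_linear"] = table

    for j, col in enumerate(_PC_STD_COLS, start=1):
        res = sm.OLS(merged[col].to_numpy(dtype=float), demo.to_numpy(dtype=float)).fit()
        ci = res.conf_int()
        table = _coef_table(res.params, res.bse, (ci[:, 0], ci[:, 1]), res.pvalues)
        table.index = demo.columns
        out[f"pc{j}_linear"] = table

    pc_design = pd.DataFrame({"intercept": np.ones(len(merged))})
    for col in _PC_STD_COLS:
        pc_design[col] = merged[col].to_numpy(dtype=float)
    out["inadequate_on_pcs"] = _fit_logit(pc_design, inadequate)
    return out
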