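"""End-to-end orchestration: simulate/load -> fit -> screen -> fPCA -> stage two.

Stages run in a fixed order with every intermediate persisted when an
output directory is given, so any stage can be re-run from artifacts.
Randomness is controlled by a single pipeline seed: per-curve restart
streams are spawned from it, so reruns with the same config reproduce all
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ackerman import AckermanFit, FitConfig, compute_bounds, fit_curve
from .curves import MG_ML_TO_MG_DL, OGTTCurve, curves_to_frame, read_curves_csv
from .errors import DegenerateBoundsError, DegenerateCohortError, SeparationError
from .fpca import BasisSpec, compute_fpca, fpc_scores, mean_curve, reconstruct, select_lambda_gcv, smooth_curve
from .screening import FitClassification, ScreeningThresholds, classify, exclude_pre_fit
from .stage_two import (
    build_gait_design,
    fit_cox_models,
    fit_gait_models,
    fit_auxiliary_models,
    frame_to_records,
    records_to_frame,
    standardize_summaries,
)
from .synthetic import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "residual_diagnostics"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one end-to-end run.

    Inputs come either from a simulation config or from CSV paths (wide
    curve table in mg/dL plus a covariate/outcome table).  fpca_lambda=None
    selects the roughness penalty by GCV.
    """

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    curves_csv: str | None = None
    records_csv: str | None = None
    output_dir: str | None = None
    max_starts: int = 1000
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    basis: BasisSpec = field(default_factory=BasisSpec)
    fpca_lambda: float | None = None
    n_retained: int = 3
    fpca_adequate_only: bool = False
    gait_models: tuple[str, ...] = ("1", "2", "3", "4", "fpc")
    seed: int = 0


@dataclass
class RunReport:
    """Counts, fPCA summaries and model tables for one run."""

    n_total: int
    n_excluded: int
    n_classified: int
    n_adequate: int
    n_inadequate: int
    n_boundary: int
    n_extrapolated: int
    n_low_r2: int
    lambda_used: float
    variance_proportions: list[float]
    tables: dict[str, pd.DataFrame]
    skipped: dict[str, str]
    residuals: dict[str, pd.DataFrame]
    config_fingerprint: dict

    def __post_init__(self):
        if self.n_excluded + self.n_classified != self.n_total:
            raise ValueError("count invariant violated: excluded + classified != total")
        if self.n_adequate + self.n_inadequate != self.n_classified:
            raise ValueError("count invariant violated: adequate + inadequate != classified")

    def counts(self) -> dict[str, int]:
        return {
            "total": self.n_total,
            "excluded": self.n_excluded,
            "classified": self.n_classified,
            "adequate": self.n_adequate,
            "inadequate": self.n_inadequate,
            "boundary": self.n_boundary,
            "extrapolated": self.n_extrapolated,
            "low_r2": self.n_low_r2,
        }


def _fit_table(fits: dict[str, AckermanFit]) -> pd.DataFrame:
    rows = []
    for pid, f in fits.items():
        rows.append(
            {
                "participant_id": pid,
                "y_F": f.params.y_F,
                "A": f.params.A,
                "k": f.params.k,
                "omega": f.params.omega,
                "t_eff": f.t_eff,
                "rss": f.rss,
                "pseudo_r2": f.pseudo_r2,
                "n_starts_used": f.n_starts_used,
                "converged": f.converged,
                "bound_yF_upper": f.bounds.upper[0],
                "bound_A_upper": f.bounds.upper[1],
            }
        )
    return pd.DataFrame(rows)


def _classification_table(cls: dict[str, FitClassification], thresholds) -> pd.DataFrame:
    rows = [
        {
            "participant_id": pid,
            "boundary": c.boundary,
            "extrapolated": c.extrapolated,
            "low_r2": c.low_r2,
            "adequate": c.adequate,
            "delta_tol": thresholds.delta_tol,
            "r2_cutoff": thresholds.r2_cutoff,
            "boundary_rel_tol": thresholds.boundary_rel_tol,
        }
        for pid, c in cls.items()
    ]
    return pd.DataFrame(rows)


def residual_diagnostics(
    fits: dict[str, AckermanFit],
    fpca_predictions: dict[str, np.ndarray],
    curves: list[OGTTCurve],
    classifications: dict[str, FitClassification] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-timepoint residual quartiles and mean RSS by method and stratum.

    fpca_predictions maps participant_id to reconstructed glucose at the 7
    sample times (mg/mL).  RSS is reported in mg^2/dL^2, the scale the
    clinical literature uses.
    """
    ids = {c.participant_id for c in curves}
    if set(fits) != ids or set(fpca_predictions) != ids:
        raise ValueError("participant sets of fits, predictions and curves differ")
    curve_map = {c.participant_id: c for c in curves}
    per_tp = []
    rss_rows = []
    resid = {"ackerman": [], "fpca": []}
    adequate_mask = []
    from .ackerman import evaluate_model

    for pid in sorted(ids):
        curve = curve_map[pid]
        ack_pred = evaluate_model(fits[pid].params, curve.times)
        resid["ackerman"].append(curve.glucose - ack_pred)
        resid["fpca"].append(curve.glucose - np.asarray(fpca_predictions[pid]))
        adequate_mask.append(
            classifications[pid].adequate if classifications is not None else True
        )
    adequate_mask = np.array(adequate_mask)
    scale = MG_ML_TO_MG_DL
    for method in ("ackerman", "fpca"):
        r = np.stack(resid[method]) * scale  # mg/dL
        for j, t in enumerate(curves[0].times):
            q1, med, q3 = np.percentile(r[:, j], [25, 50, 75])
            per_tp.append(
                {"method": method, "time_hours": t, "q1": q1, "median": med, "q3": q3}
            )
        rss_all = np.sum(r**2, axis=1)
        rss_rows.append({"method": method, "stratum": "all", "mean_rss_mg2_dl2": rss_all.mean()})
        if adequate_mask.any():
            rss_rows.append(
                {
                    "method": method,
                    "stratum": "adequate",
                    "mean_rss_mg2_dl2": rss_all[adequate_mask].mean(),
                }
            )
    return {
        "per_timepoint": pd.DataFrame(per_tp),
        "mean_rss": pd.DataFrame(rss_rows),
    }


def _spawn_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Execute all stages and return the run report.

    Stage order: acquire data, pre-fit exclusion, Ackerman fitting,
    adequacy screening, fPCA, stage-two and auxiliary models, residual
    diagnostics.  Artifacts are written under ``config.output_dir`` when
    set.  Models that are inestimable on the given cohort (for example the
    inadequacy logistic when every fit is adequate) are skipped and noted
    in ``report.skipped`` rather than aborting the run.
    """
    config = config or PipelineConfig()
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- data acquisition -------------------------------------------------
    records_df = None
    if config.curves_csv is not None:
        curves = read_curves_csv(config.curves_csv)
        if config.records_csv is not None:
            records_df = pd.read_csv(config.records_csv, dtype={"participant_id": str})
    else:
        cohort = simulate_cohort(config.simulation)
        curves = cohort.curves
        records_df = records_to_frame(cohort.records)
        if out_dir:
            cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    if out_dir:
        curves_to_frame(curves).to_csv(out_dir / "curves.csv", index=False)
        if records_df is not None:
            records_df.to_csv(out_dir / "records.csv", index=False)

    # --- pre-fit exclusion ------------------------------------------------
    kept, excluded_ids = [], []
    for curve in curves:
        if exclude_pre_fit(curve):
            excluded_ids.append(curve.participant_id)
        else:
            kept.append(curve)

    # --- Ackerman fitting and screening -----------------------------------
    seeds = _spawn_seeds(config.seed, len(kept))
    fits: dict[str, AckermanFit] = {}
    classifications: dict[str, FitClassification] = {}
    fitted_curves: list[OGTTCurve] = []
    for curve, curve_seed in zip(kept, seeds):
        try:
            bounds = compute_bounds(curve)
        except DegenerateBoundsError:
            excluded_ids.append(curve.participant_id)
            continue
        fit = fit_curve(
            curve,
            bounds,
            FitConfig(max_starts=config.max_starts, seed=curve_seed, thresholds=config.thresholds),
        )
        fits[curve.participant_id] = fit
        classifications[curve.participant_id] = classify(fit, curve, bounds, config.thresholds)
        fitted_curves.append(curve)

    fits_df = _fit_table(fits)
    class_df = _classification_table(classifications, config.thresholds)
    if out_dir:
        fits_df.to_csv(out_dir / "ackerman_fits.csv", index=False)
        class_df.to_csv(out_dir / "classifications.csv", index=False)

    # --- fPCA --------------------------------------------------------------
    fpca_input = (
        [c for c in fitted_curves if classifications[c.participant_id].adequate]
        if config.fpca_adequate_only
        else fitted_curves
    )
    lam = (
        config.fpca_lambda
        if config.fpca_lambda is not None
        else select_lambda_gcv(fpca_input, config.basis)
    )
    smoothed_all = {
        c.participant_id: smooth_curve(c, config.basis, lam) for c in fitted_curves
    }
    model = compute_fpca(
        [smoothed_all[c.participant_id] for c in fpca_input],
        n_retained=config.n_retained,
    )
    scores = {pid: fpc_scores(s, model) for pid, s in smoothed_all.items()}
    scores_df = pd.DataFrame(
        [
            {"participant_id": pid, **{f"pc{j+1}": s.scores[j] for j in range(config.n_retained)}}
            for pid, s in scores.items()
        ]
    )
    if out_dir:
        scores_df.to_csv(out_dir / "fpc_scores.csv", index=False)
        grid = np.linspace(*config.basis.domain, 401)
        fpca_out = pd.DataFrame({"time_hours": grid, "mean_mg_dl": model.mean_function(grid) * MG_ML_TO_MG_DL})
        for j in range(config.n_retained):
            fpca_out[f"phi{j+1}"] = model.eigenfunction(j)(grid)
        fpca_out.to_csv(out_dir / "fpca_functions.csv", index=False)

    # --- stage-two and auxiliary models ------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    summaries = None
    if records_df is not None and len(fits_df) > 0:
        try:
            summaries = standardize_summaries(fits_df, class_df, scores_df)
        except (DegenerateCohortError, ValueError) as err:
            skipped["stage_two"] = str(err)
    if summaries is not None:
        for model_id in config.gait_models:
            try:
                design, gait = build_gait_design(records_df, summaries, model_id)
                tables[f"gait_model_{model_id}"] = fit_gait_models(design, gait)
            except (ValueError, DegenerateCohortError) as err:
                skipped[f"gait_model_{model_id}"] = str(err)
        for spec_name in ("ackerman", "fpc"):
            try:
                tables[f"cox_{spec_name}"] = fit_cox_models(records_df, summaries, spec_name)
            except (ValueError, DegenerateCohortError) as err:
                skipped[f"cox_{spec_name}"] = str(err)
        try:
            tables.update(fit_auxiliary_models(records_df, summaries, class_df))
        except (SeparationError, ValueError, DegenerateCohortError) as err:
            skipped["auxiliary"] = str(err)
    if out_dir:
        if summaries is not None:
            summaries.to_csv(out_dir / "summaries.csv", index=False)
        for name, table in tables.items():
            table.to_csv(out_dir / f"model_{name}.csv")

    # --- residual diagnostics ----------------------------------------------
    from .curves import TIME_GRID_HOURS

    fpca_pred = {pid: reconstruct(scores[pid], model)(TIME_GRID_HOURS) for pid in fits}
    residuals = residual_diagnostics(fits, fpca_pred, fitted_curves, classifications)
    if out_dir:
        residuals["per_timepoint"].to_csv(out_dir / "residuals_per_timepoint.csv", index=False)
        residuals["mean_rss"].to_csv(out_dir / "residuals_mean_rss.csv", index=False)

    # --- report --------------------------------------------------------------
    n_adequate = sum(c.adequate for c in classifications.values())
    config_dict = _jsonable(config)
    for path_field in ("curves_csv", "records_csv", "output_dir"):
        config_dict.pop(path_field, None)  # paths do not affect the computation
    fingerprint = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
    }
    report = RunReport(
        n_total=len(curves),
        n_excluded=len(excluded_ids),
        n_classified=len(classifications),
        n_adequate=n_adequate,
        n_inadequate=len(classifications) - n_adequate,
        n_boundary=sum(c.boundary for c in classifications.values()),
        n_extrapolated=sum(c.extrapolated for c in classifications.values()),
        n_low_r2=sum(c.low_r2 for c in classifications.values()),
        lambda_used=float(lam),
        variance_proportions=[float(v) for v in model.variance_proportions[: config.n_retained]],
        tables=tables,
        skipped=skipped,
        residuals=residuals,
        config_fingerprint=fingerprint,
    )
    if out_dir:
        payload = {
            "counts": report.counts(),
            "lambda_used": report.lambda_used,
            "variance_proportions": report.variance_proportions,
            "excluded_participants": sorted(excluded_ids),
            "skipped": skipped,
            "fingerprint": fingerprint,
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return report


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
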