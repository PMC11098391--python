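"""Unit tests for standardization, design construction and outcome models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ogttkit import (
    OutcomeCoefficients,
    SimulationConfig,
    build_gait_design,
    fit_auxiliary_models,
    fit_cox_models,
    fit_gait_models,
    simulate_cohort,
    standardize_summaries,
)
from ogttkit.errors import DegenerateCohortError, SeparationError
from ogttkit.stage_two import (
    GAIT_MODEL_COLUMNS,
    age_spline_basis,
    records_to_frame,
    standardize_table,
)


def toy_inputs(n=40, n_inadequate=10, seed=0):
    """Plausible fit/classification/score tables without running the fitter."""
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n)]
    fits = pd.DataFrame(
        {
            "participant_id": ids,
            "y_F": rng.uniform(0.8, 1.2, n),
            "A": rng.uniform(0.4, 1.8, n),
            "k": rng.uniform(0.6, 2.8, n),
            "omega": rng.uniform(1.2, 4.2, n),
        }
    )
    fits["t_eff"] = 2 * np.pi / np.hypot(fits["k"], fits["omega"])
    adequate = np.ones(n, dtype=bool)
    adequate[:n_inadequate] = False
    cls = pd.DataFrame({"participant_id": ids, "adequate": adequate})
    scores = pd.DataFrame(
        {
            "participant_id": ids,
            "pc1": rng.normal(0, 0.5, n) - 0,
            "pc2": rng.normal(0, 0.2, n),
            "pc3": rng.normal(0, 0.1, n),
        }
    )
    for c in ("pc1", "pc2", "pc3"):
        scores[c] -= scores[c].mean()
    return fits, cls, scores


def toy_records(n=40, seed=1, missing_smoking=0):
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "age": rng.uniform(50, 95, n),
            "bmi": rng.uniform(18, 40, n),
            "sex": rng.choice(["male", "female"], n),
            "race": rng.choice(["White", "Black", "NonWhiteNonBlack"], n, p=[0.6, 0.3, 0.1]),
            "smoking": rng.choice(["ever", "never"], n),
            "gait_speed": rng.uniform(0.5, 1.6, n),
            "survival_time": rng.uniform(0.5, 15, n),
            "event": rng.integers(0, 2, n),
        }
    )
    if missing_smoking:
        rec.loc[: missing_smoking - 1, "smoking"] = None
    return rec


class TestStandardizeSummaries:
    def test_all_adequate_gives_unit_scale_columns(self):
        fits, cls, scores = toy_inputs(n_inadequate=0)
        out = standardize_summaries(fits, cls, scores)
        assert (out["adequate_indicator"] == 1).all()
        for col in ("log_yF_std", "log_A_std", "k_std", "omega_std", "teff_std"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_inadequate_rows_are_gated_to_zero(self):
        fits, cls, scores = toy_inputs(n_inadequate=10)
        out = standardize_summaries(fits, cls, scores)
        gated = out[out["adequate_indicator"] == 0]
        assert len(gated) == 10
        for col in ("log_yF_std", "log_A_std", "k_std", "omega_std", "teff_std"):
            assert (gated[col] == 0.0).all()
        assert gated["teff_hours"].isna().all()

    def test_pc_columns_scaled_not_centered(self):
        fits, cls, scores = toy_inputs()
        out = standardize_summaries(fits, cls, scores)
        for j in (1, 2, 3):
            assert out[f"pc{j}_std"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
            assert out[f"pc{j}_std"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_standardization_is_idempotent(self):
        fits, cls, scores = toy_inputs()
        out = standardize_summaries(fits, cls, scores)
        cols = [
            "log_yF_std", "log_A_std", "k_std", "omega_std", "teff_std",
            "pc1_std", "pc2_std", "pc3_std",
        ]
        again = standardize_table(out[cols].copy(), out["adequate_indicator"])
        assert np.max(np.abs(again[cols].to_numpy() - out[cols].to_numpy())) < 1e-12

    def test_zero_spread_column_rejected(self):
        fits, cls, scores = toy_inputs()
        fits["k"] = 1.5  # constant across the cohort
        with pytest.raises(DegenerateCohortError):
            standardize_summaries(fits, cls, scores)


class TestBuildGaitDesign:
    def test_model_2_has_exactly_two_summary_columns(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        design2, _ = build_gait_design(toy_records(), summaries, "2")
        design_fpc, _ = build_gait_design(toy_records(), summaries, "fpc")
        assert GAIT_MODEL_COLUMNS["2"] == ["adequate_indicator", "teff_std"]
        assert set(design2.columns) - set(design_fpc.columns) == {"adequate_indicator", "teff_std"}
        assert design2.shape[1] == design_fpc.shape[1] - 1  # 2 summary cols vs 3 PC cols

    def test_inadequate_rows_zero_in_model_1(self):
        fits, cls, scores = toy_inputs(n_inadequate=10)
        summaries = standardize_summaries(fits, cls, scores)
        design, _ = build_gait_design(toy_records(), summaries, "1")
        gated = design[design["adequate_indicator"] == 0]
        assert (gated[["log_yF_std", "k_std", "omega_std"]] == 0).all().all()

    def test_unknown_model_rejected(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        with pytest.raises(ValueError):
            build_gait_design(toy_records(), summaries, "5")

    def test_missing_smoking_rows_dropped(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        design, gait = build_gait_design(toy_records(missing_smoking=6), summaries, "2")
        assert len(design) == len(gait) == 40 - 6

    def test_age_spline_matches_cox_de_boor_recursion(self):
        ages = np.array([55.0, 65.0, 70.0, 75.0, 85.0, 90.0])
        lo, hi = ages.min(), ages.max()
        knots = np.concatenate([[lo] * 4, [65.0, 75.0, 85.0], [hi] * 4])

        def bspline_basis(x, j, d):
            # textbook Cox-de Boor recursion; the domain endpoint belongs to
            # the last non-empty knot interval
            if d == 0:
                closes_domain = knots[j] < knots[j + 1] == hi
                if (knots[j] <= x < knots[j + 1]) or (closes_domain and x == hi):
                    return 1.0
                return 0.0
            left, right = 0.0, 0.0
            if knots[j + d] > knots[j]:
                left = (x - knots[j]) / (knots[j + d] - knots[j]) * bspline_basis(x, j, d - 1)
            if knots[j + d + 1] > knots[j + 1]:
                right = (
                    (knots[j + d + 1] - x)
                    / (knots[j + d + 1] - knots[j + 1])
                    * bspline_basis(x, j + 1, d - 1)
                )
            return left + right

        basis = age_spline_basis(ages, boundary=(lo, hi))
        n_basis = basis.shape[1] + 1  # first column dropped for the intercept
        for i, age in enumerate(ages):
            oracle = [bspline_basis(age, j, 3) for j in range(n_basis)]
            ours = basis.iloc[i].to_numpy()
            assert np.allclose(ours, oracle[1:], atol=1e-12)


class TestFitGaitModels:
    def test_duplicated_column_is_singular(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        design, gait = build_gait_design(toy_records(), summaries, "2")
        design["dup"] = design["teff_std"]
        with pytest.raises(ValueError):
            fit_gait_models(design, gait)

    def test_covariate_rescaling_is_linear_reparameterization(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(50, 95, 300)
        y = 0.8 - 0.004 * age + rng.normal(0, 0.05, 300)
        d10 = pd.DataFrame({"intercept": 1.0, "age_scaled": age / 10})
        d20 = pd.DataFrame({"intercept": 1.0, "age_scaled": age / 20})
        c10 = fit_gait_models(d10, pd.Series(y)).loc["age_scaled", "coef"]
        c20 = fit_gait_models(d20, pd.Series(y)).loc["age_scaled", "coef"]
        assert c20 == pytest.approx(2 * c10, rel=1e-10)

    def test_gating_equivalence_without_shared_covariates(self):
        """With only an intercept, the adequate-fit indicator and a gated
        summary column, the full-cohort fit estimates the same summary
        coefficient as an adequate-only regression."""
        rng = np.random.default_rng(7)
        n = 500
        adequate = rng.random(n) < 0.7
        x = np.where(adequate, rng.normal(size=n), 0.0)
        y = 1.0 - 0.04 * (~adequate) + 0.03 * x + rng.normal(0, 0.1, n)
        full = pd.DataFrame({"intercept": 1.0, "adequate_indicator": adequate.astype(float), "x": x})
        coef_full = fit_gait_models(full, pd.Series(y)).loc["x", "coef"]
        sub = pd.DataFrame({"intercept": 1.0, "x": x[adequate]})
        coef_sub = fit_gait_models(sub, pd.Series(y[adequate])).loc["x", "coef"]
        assert coef_full == pytest.approx(coef_sub, rel=1e-10)

    def test_row_order_invariance(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        design, gait = build_gait_design(toy_records(), summaries, "2")
        perm = np.random.default_rng(3).permutation(len(design))
        t1 = fit_gait_models(design, gait)
        t2 = fit_gait_models(design.iloc[perm].reset_index(drop=True), gait.iloc[perm].reset_index(drop=True))
        assert np.allclose(t1["coef"], t2["coef"], atol=1e-12)


class TestFitCoxModels:
    def test_null_hazard_ratios_center_on_one(self):
        null = OutcomeCoefficients(loghr_latent=0.0)
        cohort = simulate_cohort(
            SimulationConfig(n_participants=1500, fraction_atypical=0.0, seed=23,
                             outcome_coefficients=null)
        )
        rec = records_to_frame(cohort.records)
        rng = np.random.default_rng(1)
        summaries = pd.DataFrame(
            {
                "participant_id": cohort.truth["participant_id"],
                "pc1_std": rng.normal(size=1500),
                "pc2_std": cohort.truth["latent"],
                "pc3_std": rng.normal(size=1500),
                "adequate_indicator": 1.0,
                "teff_std": 0.0,
            }
        )
        table = fit_cox_models(rec, summaries, "fpc")
        assert abs(table.loc["pc2_std", "coef"]) < 3 * table.loc["pc2_std", "se"]

    def test_known_hazard_ratio_recovered(self):
        cohort = simulate_cohort(SimulationConfig(n_participants=2000, fraction_atypical=0.0, seed=29))
        rec = records_to_frame(cohort.records)
        rng = np.random.default_rng(2)
        summaries = pd.DataFrame(
            {
                "participant_id": cohort.truth["participant_id"],
                "pc1_std": rng.normal(size=2000),
                "pc2_std": cohort.truth["latent"],
                "pc3_std": rng.normal(size=2000),
                "adequate_indicator": 1.0,
                "teff_std": 0.0,
            }
        )
        table = fit_cox_models(rec, summaries, "fpc")
        target = np.log(0.80)
        assert abs(table.loc["pc2_std", "coef"] - target) < 3 * table.loc["pc2_std", "se"]

    def test_no_events_rejected(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        rec = toy_records()
        rec["event"] = 0
        with pytest.raises(ValueError):
            fit_cox_models(rec, summaries, "ackerman")

    def test_unknown_spec_rejected(self):
        fits, cls, scores = toy_inputs()
        summaries = standardize_summaries(fits, cls, scores)
        with pytest.raises(ValueError):
            fit_cox_models(toy_records(), summaries, "bayes")


class TestAuxiliaryModels:
    def test_teff_regression_uses_adequate_fits_only(self):
        fits, cls, scores = toy_inputs(n_inadequate=10)
        summaries = standardize_summaries(fits, cls, scores)
        rec = toy_records()
        tables = fit_auxiliary_models(rec, summaries, cls)
        # oracle: direct OLS on the adequate subset
        merged = rec.merge(summaries, on="participant_id").merge(cls, on="participant_id")
        sub = merged[merged["adequate"]]
        X = np.column_stack(
            [
                np.ones(len(sub)),
                sub["age"] / 10,
                sub["bmi"] / 5,
                (sub["sex"] == "male").astype(float),
                (sub["race"] == "White").astype(float),
                (sub["race"] == "NonWhiteNonBlack").astype(float),
                (sub["smoking"] == "ever").astype(float),
            ]
        )
        oracle = sm.OLS(sub["teff_hours"].to_numpy(), X).fit()
        assert int(oracle.nobs) == int(cls["adequate"].sum())
        assert np.allclose(tables["teff_linear"]["coef"].to_numpy(), oracle.params, atol=1e-10)

    def test_single_adequacy_class_raises_separation(self):
        fits, cls, scores = toy_inputs(n_inadequate=0)
        summaries = standardize_summaries(fits, cls, scores)
        with pytest.raises(SeparationError):
            fit_auxiliary_models(toy_records(), summaries, cls)

    def test_logistic_slope_on_pc_score_recovered(self):
        rng = np.random.default_rng(31)
        n = 2000
        ids = [f"P{i:04d}" for i in range(n)]  # must match toy_records ids
        pc2 = rng.normal(size=n)
        logit_p = -0.5 + 0.7 * pc2
        inadequate = rng.random(n) < 1 / (1 + np.exp(-logit_p))
        fits = pd.DataFrame(
            {
                "participant_id": ids,
                "y_F": rng.uniform(0.8, 1.2, n),
                "A": rng.uniform(0.4, 1.8, n),
                "k": rng.uniform(0.6, 2.8, n),
                "omega": rng.uniform(1.2, 4.2, n),
            }
        )
        fits["t_eff"] = 2 * np.pi / np.hypot(fits["k"], fits["omega"])
        cls = pd.DataFrame({"participant_id": ids, "adequate": ~inadequate})
        scores = pd.DataFrame(
            {
                "participant_id": ids,
                "pc1": rng.normal(size=n),
                "pc2": pc2 - pc2.mean(),
                "pc3": rng.normal(size=n),
            }
        )
        rec = toy_records(n, seed=6)
        tables = fit_auxiliary_models(rec, standardize_summaries(fits, cls, scores), cls)
        row = tables["inadequate_on_pcs"].loc["pc2_std"]
        # slope estimated per SD of the score; truth scaled accordingly
        truth = 0.7 * scores["pc2"].std(ddof=1)
        assert abs(row["coef"] - truth) < 3 * row["se"]
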