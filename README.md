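# ogttkit

Two-stage modeling of oral glucose tolerance test (OGTT) curves for aging
research: a parametric glucose-insulin model with principled fit-adequacy
screening, a nonparametric functional-PCA summary, and regression models
linking both kinds of curve summaries to usual gait speed and survival.

## The problem

During a 75 g OGTT, plasma glucose is drawn at 0, 20, ..., 120 minutes,
giving each participant a 7-point response curve. Dynamical-systems
thinking suggests that *how* the glucose-insulin system responds to this
standardized stressor — how fast it peaks, how quickly it recovers —
carries information about physiological resilience and hence about
age-related outcomes such as slow gait and mortality. Two stage-one
summaries are computed per curve:

**Ackerman model.** The closed-form impulse response of a linearized
glucose-insulin system,

    Y(t) = Y_F + A · e^(−kt) · sin(ωt),

with fasting glucose `Y_F` (mg/mL), amplitude `A` (mg/mL), damping `k`
(1/h) and frequency `ω` (1/h). The derived effective period
`T_eff = 2π / √(ω² + k²)` is the recovery time scale of the system.
Fitting is box-constrained nonlinear least squares (parameters bounded by
`Y_F ∈ [0, 2Y(0)]`, `A ∈ [0, 20(max Y − Y(0))]`, `k ∈ [0, 10]`,
`ω ∈ [0, 2π]` for biological plausibility), started from all-ones and
restarted from uniform draws over the box — up to 1,000 starts — until a
satisfactory fit is found. Because many real curves are not damped
sinusoids, every fit is screened and labeled **adequate** or
**inadequate** by three non-exclusive criteria:

1. *boundary fits* — estimates pinned to the parameter box (a symptom of
   practical non-identifiability);
2. *extrapolated fits* — predicted peak within the 2 h window missing the
   observed peak by ≥ 10% in relative terms (over- or under-shoot);
3. *low pseudo-R²* — `1 − RSS/TSS < 0.7`.

Curves whose 20-minute glucose is strictly below baseline are excluded
before fitting. Inadequate parameter estimates are not interpreted: in
stage two they are gated to zero behind an adequate-fit indicator.

**Functional PCA.** Each curve is smoothed with six cubic B-splines on
[0, 2] h under a second-derivative roughness penalty (weight chosen by
generalized cross-validation), and the smoothed cohort is decomposed into
a mean curve, orthonormal eigenfunctions φ_j and per-participant scores
η_ij = ∫ φ_j(t)(x_i(t) − x̄(t)) dt. The first three components are
retained.

**Stage two.** Standardized summaries (log Y_F, k, ω, T_eff among adequate
fits; fPC scores scaled by cohort SD) enter linear models of usual gait
speed (cubic age spline, knots 65/75/85) and Cox proportional-hazards
models of death (linear age), both adjusted for BMI, sex, race and smoking
history. Auxiliary models relate the summaries to demographics.

Because the motivating cohort data are not public, the package ships a
synthetic cohort generator (`ogttkit.synthetic`) that reproduces the
assumed statistical structure — typical damped-sinusoid curves plus
atypical shapes (biphasic, continuous-rise, oscillating, early-drop),
demographics, and outcomes generated from known coefficients — so every
stage is testable end to end.

## Worked example

`examples/` contains one short script per capability. Fitting a single
noisy curve (`python examples/01_fit_single_curve.py`):

```
observed glucose (mg/dL): [ 98.5 129.1 140.1 126.4  95.6  88.2  91.5]

               truth  estimate
Y_F (mg/mL)    0.970     1.016
A   (mg/mL)    0.900     0.561
k   (1/h)      1.200     0.677
omega (1/h)    2.000     2.389

effective period T_eff = 2.53 h (recovery time scale of the glucose-insulin
system; ~4 h and above historically read as sluggish regulation)
RSS = 109 mg^2/dL^2, pseudo-R2 = 0.960, starts used = 1
```

With 5 mg/dL noise on seven points the individual parameters are only
loosely identified (the fitted curve is nonetheless excellent — pseudo-R²
0.96), which is exactly why the screening stage and the cohort-level
regressions matter. Recovering known outcome effects on a simulated
cohort of 3,000 (`python examples/04_outcome_models.py`):

```
gait speed model (m/s per SD of the latent feature):
  estimate 0.0187  95% CI (0.0133, 0.0242)  p = 1.8e-11   [truth 0.02]
Cox model (hazard ratio per SD of the latent feature):
  HR 0.786  95% CI (0.743, 0.833)  p = 1.89e-16   [truth 0.80]
```

The full pipeline (simulate → fit → screen → fPCA → stage two → report)
runs as a library call (`run_pipeline`) or from the shell:

```bash
ogttkit run-all out/ --n 250 --seed 4
```

and writes every intermediate table (fits, classifications, scores,
model coefficients) as CSV plus a JSON report; identical config and seed
reproduce all artifacts bit-identically.

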