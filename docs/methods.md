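# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the limitations of `ogttkit`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stage one: the Ackerman model

A linearized glucose-insulin system driven by an impulse of glucose at
t = 0 has the closed-form response

    Y(t) = Y_F + A e^(−kt) sin(ωt),

with fasting glucose `Y_F` and amplitude `A` in mg/mL and rates `k`, `ω`
in 1/h. All computation uses mg/mL and hours internally — this puts the
four parameters on comparable scales (roughly 0–10), which conditions the
optimization — while file I/O uses the clinical mg/dL (factor 100,
converted at the boundary). Individual curves add homoscedastic mean-zero
measurement error at the seven sample times.

The model is assumed, not tested: it treats all regulatory hormones as
one, and models intestinal glucose absorption as instantaneous. Real
cohorts contain curves (multiple peaks, monotone rise, a drop in the
first 20 minutes) that no damped sinusoid fits; the screening stage
exists because of this.

### Fitting

Per curve, `fit_curve` minimizes the sum of squared residuals over the
seven grid points subject to the biological box `Y_F ∈ [0, 2Y(0)]`,
`A ∈ [0, 20(max Y − Y(0))]`, `k ∈ [0, 10]`, `ω ∈ [0, 2π]`. The lower
bounds are physiological (negative values imply negative fasting glucose,
an initial glucose decline, or growing oscillations); the upper bounds
make convergence practical on a multimodal least-squares surface. A flat
or never-rising curve collapses the `A` interval and raises a
degenerate-bounds error.

The optimizer is `scipy.optimize.least_squares` (trust-region reflective)
with the analytic Jacobian and ftol = xtol = gtol = 1e-12, so restart
coverage rather than loose tolerances governs fit quality. The first
start is all-ones; if the converged fit would be classified inadequate,
fitting restarts from uniform draws over the box, by default up to 1,000
starts in total (`FitConfig.max_starts`). The first satisfactory fit
wins; otherwise the minimum-RSS converged fit is returned, ties broken by
earliest start. Restart draws use one integer seed per curve; the
pipeline spawns per-curve seeds from its single global seed
(`numpy.random.SeedSequence`), so runs are bit-reproducible.

The pipeline, examples and acceptance script pass smaller explicit caps
(10–60 starts) as their problem-size choice: a curve that no damped
sinusoid fits adequately will spend the entire budget without changing
its classification, and the best RSS typically stops improving within a
few dozen starts.

### Screening

Three non-exclusive criteria mark a fit inadequate
(`ScreeningThresholds`):

- **boundary** — any estimate within `boundary_rel_tol = 1e-4` of either
  end of its bound interval, measured as a fraction of the interval
  width. The tolerance is a numerical reading of "on the boundary"; it is
  applied at both ends of all four parameters for symmetry.
- **extrapolated** — the analytic peak of the fitted curve
  (`t_max = arctan(ω/k)/ω` for k > 0, `π/2ω` for k = 0) occurs within the
  2 h test window *and* `|Y_max,pred − Y_max,obs| / Y_max,obs ≥ δ_tol`
  with `δ_tol = 0.10`. The during-test condition protects well-fitting
  but slow-peaking curves; the absolute value catches severe
  under-prediction as well as over-shoot. The observed maximum is the
  maximum over the seven grid points, with no interpolation correction —
  the true peak almost certainly falls between draws, so the criterion is
  deliberately not made stricter.
- **low pseudo-R²** — `1 − RSS/TSS < 0.7`, i.e. the fit barely improves
  on an intercept-only model. Absolute RSS is a poor screen (large RSS
  can accompany visually good fits and vice versa); the relative measure
  tracks visual adequacy better.

A fit is adequate iff no flag fires. Curves with 20-minute glucose
strictly below baseline (`Y(20) < Y(0)`) are excluded before fitting;
ties are kept, since a tie is not a decline. Classification applies to
the final returned fit only. Degenerate corner: a fit with `ω̂ = 0`
predicts a constant curve; its "peak" is taken as `Y_F` at t = 0 so
screening needs no special case (such fits are boundary fits anyway).

## Stage one: functional PCA

Each curve is smoothed by penalized least squares in a cubic B-spline
basis with 6 functions on [0, 2] h. Six cubic functions force two
interior knots, placed at 2/3 and 4/3 h (equally spaced; knot placement
is otherwise immaterial at this resolution). The objective is

    Σ_t (Y_t − x(t))² + λ ∫ x″(t)² dt.

λ is selected by generalized cross-validation,
`GCV(λ) = n·SSE/(n − df(λ))²` with df the trace of the smoothing hat
matrix, averaged over curves and minimized over a 50-point log-spaced
grid from 1e-2 to 1e5 (ties toward smaller λ). λ can be pinned in config;
the GCV optimum is data-specific, and on synthetic cohorts — whose
seven points carry more independent curve-to-curve variation than smooth
biological curves do — GCV tends to choose very light smoothing.

The eigenproblem is solved in the basis-coefficient domain: with Gram
matrix `G` (basis inner products) and centered coefficient rows `D`, the
eigenvectors of `G^{1/2} (DᵀD/n) G^{1/2}` map through `G^{-1/2}` to
eigenfunction coefficients orthonormal under the L² inner product.
Variance proportions are eigenvalue shares of the total. Scores are exact
Gram-matrix inner products; the cohort mean of every score is zero by
construction. Three components are retained by default.

Sign convention: each eigenfunction is flipped so its integral over
[0, 2] is positive; if the integral is below 1e-10 in magnitude, the
value at t = 1 h decides. This makes score signs reproducible.

Quadrature: Simpson's rule on a uniform 401-point grid for L² inner
products (the Gram matrix and any grid-level checks). The roughness
penalty matrix alone is integrated exactly by per-knot-interval
Gauss-Legendre — its integrand is piecewise quadratic, and an exact
penalty keeps the straight line precisely in its null space, so the
heavy-smoothing limit degrades gracefully into the least-squares line.
Quadrature at λ as large as 1e12 is still rounding-limited in double
precision at about the 1e-4 level.

All curves that survive pre-fit exclusion enter fPCA, including those
whose Ackerman fits are inadequate (`fpca_adequate_only` supports the
restricted sensitivity variant). fPCA is a cohort-level procedure: one
participant's score depends on everyone's curves, so there is no
per-curve adequacy notion and no screening analogue.

## The synthetic cohort generator

The generator emulates a community-dwelling cohort aged 50+ with one OGTT
per person and gait/mortality follow-up.

- **Typical curves** (default 75%): parameters drawn uniformly,
  `Y_F ∈ [0.75, 1.25]`, `A ∈ [0.3, 2.0]` mg/mL, `k ∈ [0.5, 3.0]`,
  `ω ∈ [1.0, 4.5]` 1/h — strictly inside the fitting box, with the
  population mean curve landing near published older-cohort landmarks: a
  fasting level near 100 mg/dL and a peak near 150 mg/dL within the first
  hour (`scripts/acceptance.py` reports the realized values). Noise is
  iid Gaussian, SD 0.05 mg/mL (5 mg/dL), typical assay scale.
- **Atypical curves** (default 25%, uniform over four shapes): piecewise
  constructions, deliberately not Ackerman-based — biphasic (exactly two
  interior peaks), continuous rise (strictly increasing), oscillating
  (alternating ±≥ 20 mg/dL steps), early drop (20-min glucose below
  baseline, triggering pre-fit exclusion).
- **Demographics**: age ~ U(50, 95); BMI ~ N(27, 4.5²) clipped to
  [16, 45]; 48% male; race White/Black/other 65/25/10%; 40% ever-smokers;
  optionally a missing-smoking fraction.
- **Outcomes**: a latent curve feature — the early-minus-late mean
  glucose contrast, standardized within the cohort — stands in for the
  second fPC ("early peak, fast clearance"). Gait speed is linear in the
  latent feature (0.02 m/s per SD), age (−0.05 per 10 y), BMI (−0.02 per
  5 units) and male sex (+0.05), intercept 1.05 m/s, noise SD 0.15 m/s.
  Survival is exponential with baseline rate 0.035/y and log-hazard
  linear in the same terms (HR 0.80 per SD of the latent feature, 1.5 per
  10 y of age), administratively censored at 15 years (≈ 50% events).
  All true parameters are retained in the cohort's `truth` table.

What the generator does **not** emulate: within-person repeat visits,
insulin or incretin trajectories, parameter-demographic correlations
(curve shape is independent of age and BMI by construction), informative
censoring, and any real-data missingness beyond the optional smoking
gap. Passing tests therefore demonstrate the machinery's correctness and
calibration under the assumed structure, not its behavior on real
cohorts.

## Stage two

Ackerman summaries are log-transformed where right-skewed (Y_F, A), then
centered and scaled on the adequate-fit subcohort; for inadequate fits
every Ackerman column and the adequate-fit indicator are exactly zero.
This gating is algebraically equivalent to giving inadequate fits their
own intercept and estimating the parameter effects from adequate fits
only. fPC scores are mean-zero by construction and are scaled by the
whole-cohort SD without centering; the SD is computed per retained
component over all participants. Standardization is idempotent.

Gait-speed models are OLS with a cubic B-spline in age (interior knots at
65/75/85 y, boundary knots at the cohort age range, first basis column
dropped in favor of the intercept), BMI per 5 units, sex, race dummies
(reference: female, Black, never-smoker) and smoking. The model families:
Model 1 (indicator + log Y_F, k, ω), Models 2–4 (indicator + T_eff,
progressively adding log Y_F and k), and the fPC model (three scores).
Survival models are Cox proportional hazards via lifelines with the Efron
tie approximation and a linear age term. Auxiliary models: logistic
inadequate-fit on demographics, OLS of T_eff (hours, unstandardized) on
demographics among adequate fits, OLS of each standardized score on
demographics, and logistic inadequate-fit on the three scores. Age enters
per 10 years and BMI per 5 throughout. Records with missing smoking
history are dropped from stage-two and auxiliary models but retained in
stage one.

Coefficients for the small non-White/non-Black stratum are estimated but
should not be interpreted. Stage-one estimation uncertainty is not
propagated into stage-two standard errors; with seven points per curve
this is a real limitation for any significant stage-two effect, and a
participant-level bootstrap is the natural extension.

## Problem sizes and runtime choices

The test suite and acceptance script choose sizes that make the
statistical checks sharp while keeping runs short: 200 curves for
zero-noise parameter recovery; 100-curve cohorts for the fPCA oracle
comparisons; n = 2,000 cohorts (200 replicates for CI coverage, 500 for
null calibration) for stage-two inference; pipeline demonstrations at
60–400 participants with restart caps of 10–60. The full suite runs in
under two minutes on one core; `scripts/acceptance.py` in about half a
minute.

## Known limitations

- With seven samples and 5 mg/dL noise, individual Ackerman parameters
  are weakly identified even for truly sinusoidal curves; screening
  catches the pathological cases, not the benign imprecision.
- Large damping rates are practically non-identifiable from the grid: a
  curve generated with k well above the box can be reproduced almost
  exactly by interior parameter sets, so "boundary" is a property of the
  fit, not a test for out-of-box truth.
- GCV over seven points per curve is a weak smoother selector; the
  retained-variance pattern of synthetic cohorts depends on it.
- The exponential survival model satisfies proportional hazards by
  construction; the Cox machinery is exercised, not stress-tested.
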