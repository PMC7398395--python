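# Methods

## Structural model

Three compartments: depot A1 (mg), central A2 (mg), hair A3. Absorption
is first order (k12), elimination first order with k20 = CL/Vc, and a
fraction `frac` of every eliminated milligram is booked into the hair
compartment (dA3/dt = frac·k20·A2). Dosing is an instantaneous bolus
into A1 every τ = 24 h. Closed forms: the Bateman single-dose
concentration and the steady-state trough

    C_ss,trough = (D/Vc) · k12/(k12−k20) · [a(k20) − a(k12)],
    a(k) = e^(−kτ)/(1 − e^(−kτ)),

with the analytic limit (D/Vc)·k12·τ·e^(−k12τ)/(1−e^(−k12τ))² when
|k12−k20| < 1e−8. Both are written in `expm1` form so they neither
overflow nor lose precision at extreme rate constants. The general ODE
path (`integrate_system`, LSODA, rtol 1e−8 / atol 1e−10, configurable)
exists for trajectory work and as the oracle against the closed forms;
mass balance A3 = frac·(D_tot − A1 − A2) holds to integration
tolerance.

Plasma parameters are fixed at published steady-state values for both
analytes and scaled allometrically by body weight (exponent 0.75 on
CL/F, 1 on Vc; reference weight 70 kg, configurable — the reference
only re-labels frac_pop and cancels out of recovery).

## The hair link and the unit convention

Two readings of the hair equation are possible, and they differ in
whether the subject's plasma random effects reach the hair data:

1. **Point-trough link**: C_hair = frac_i × trough(CL_i e^η, …). Here
   η_CL enters through e^(−k20τ), with log-slope
   d ln trough/d η_CL ≈ −3.3 at the ATV constants.
2. **Accumulation link** (the package default): integrating
   dA3/dt = frac·k20·A2 over a dosing interval at steady state gives
   exactly frac × (absorbed dose) — the plasma random effects cancel
   out of hair accumulation. The hair prediction is then
   C_hair = frac_i × S_i where S_i is the weight-adjusted *typical*
   steady-state trough (the ratio convention applied at the typical
   level).

The default is the accumulation link, for two reasons. Physically, a
hair segment integrates weeks of uptake, which is a dose-rate, not a
point-concentration, quantity. Statistically, under the point-trough
link the between-subject variance of log hair concentrations is
(3.3)²·ω²_CL ≈ 11 — between-subject covariate effects (BMI, caregiver)
are then essentially unidentifiable at any realistic cohort size
(Fisher SD ≈ 0.4 for a 15% category at n=500, and measured refits
corroborate this), which is inconsistent with the small standard
errors reported for those effects in real studies of this design,
while the near-total (≈100%+) standard errors typically reported for
the plasma variance components are exactly what the accumulation link
predicts. The point-trough link remains available as
`ModelParameters(plasma_iiv_in_hair=True)` and is used by the
estimator oracle tests, where active random effects are required.

Consequence: the plasma ω² values are carried as fixed descriptors of
the plasma side; they cannot be estimated from hair-only data under
the default link (flat likelihood) and are not free parameters in the
shipped final models.

**Units.** Hair assays report ng drug per mg hair while the plasma
model works in mg/L, and no compartment bookkeeping reconciles the two
with Vh fixed at 1; the model therefore estimates a ratio and absorbs
the absolute scale. The internal trough unit is 100 × mg/L (µg/dL),
chosen once because it makes the published numbers mutually coherent
on the observed scale: frac 0.16 × ATV typical trough (0.171 mg/L →
17.1 internal units) ≈ 2.7, matching the reported mean hair
concentration of ~2.5 ng/mg, the additive error SD 0.30 and the
assay LLOQ 0.05 in the same unit. Simulation and estimation share the
convention, so frac recovery is invariant to it.

## Population model

Individual fraction: frac_i = frac_pop × Π(1 + β_k x_k) with
proportional-linear factors (occasion, adherence VAS centered at the
cohort mean 84.2, BMI-for-age, caregiver; reference levels follow-up /
normal / grandparent). This is the standard NONMEM idiom matching
"x% higher/lower" covariate reporting. Note the published adherence
coefficient (+0.02 per VAS unit) makes the factor negative below
VAS ≈ 34 — feasible under the study's observed VAS range [30, 100] —
so likelihood evaluation floors each factor at 1e−3, while the public
`individual_frac` raises a domain error naming the covariate.
Residual error is combined: sd(f) = √((sd_prop·f)² + sd_add²), with
the interaction (sd depends on the individual prediction) respected in
estimation. Optional inter-occasion variability on frac
(`omega2_frac_iov`, log-normal per occasion, default 0) is the
configuration that activates per-subject random effects under the
default hair link; it doubles as the two-dimensional test bed for the
conditional-mode machinery.

## Estimation

OFV = −2 log marginal likelihood, approximated per subject by a full
Laplace expansion at the conditional mode η̂ (empirical Bayes
estimate):

    −2 log L_i ≈ 2·negh(η̂) − d·log 2π + log det H,

with negh the negative joint log-density and H its Hessian at the
mode. The inner problem starts at η = 0 every outer iteration (no warm
start, for determinism) and is solved by a damped Newton iteration
with central finite-difference gradients and Hessians (step 5e−4,
chosen to balance second-difference roundoff against truncation),
vectorized across all subjects simultaneously; only unconverged
subjects are re-evaluated. Eigenvalues of the stepping Hessian are
floored at 0.1 so steps stay descent directions through non-convex
regions; steps are trust-region scaled (max component 3) and
backtracked on the objective with non-finite trial values treated as
failures. The Hessian used for the log-determinant is the one at the
converged mode; if it is not positive definite it is floored at 1e−8
with a logged warning. Subjects whose records are all below the
quantification limit contribute exactly zero to the OFV and are
dropped with a warning.

Outer optimization: L-BFGS-B on a transformed scale (log for frac_pop,
variances and residual SDs; bounded raw scale for the β's, lower bound
−0.999 so reference-level factors stay positive) with central
('3-point') numerical gradients — forward differences stall the line
search on this surface. An abnormal line-search termination is
accepted only if a restart from the returned point fails to improve
the OFV by more than 0.01 (the fixed-point criterion); otherwise the
restart result is taken. Starting values default to
`initial_from_data`: frac_pop = median quantifiable concentration /
typical trough (the naive-pooled estimate), which removes a degenerate
basin in which a covariate factor collapses onto its floor. Standard
errors come from the central-difference Hessian of the OFV at the
optimum (cov = 2 H⁻¹), delta-method mapped to the natural scale, and
are reported as percent of the estimate.

`quadrature_ofv` is the independent accuracy oracle: adaptive
Gauss–Hermite centered at η̂ and scaled by H^(−1/2), for up to two
active dimensions. Under the log-normal IOV link (|d ln f/dη| = 1)
Laplace agrees with 32-node quadrature to ≲0.2 OFV units on small
cohorts; under the point-trough link (|d ln f/dη| ≈ 3.3) the
conditional density is visibly skewed and the Laplace error reaches
~0.05–0.1 per subject regardless of ω² — an intrinsic property of the
approximation at that curvature, not an implementation artifact (the
linear-model toy agrees with the analytic marginal to <1e−5).

BLQ records are excluded (M1), mirroring the source analysis. M1 on a
censored cohort leaves the refit estimand slightly below the
generating value for low-concentration strata (measured: the RTV
enrolment effect recovers at ≈ −0.38 instead of −0.42 with ~5%
censoring), so estimator-validation cohorts are generated with
censoring disabled (`CohortSpec(censoring=False)`); the default
generator keeps the assay limits. Likelihood-based censoring (M3) is a
documented extension point, not implemented.

## Covariate selection, bootstrap, diagnostics

SCM: forward inclusion then backward elimination on Frac only. A
candidate enters if its OFV drop exceeds the χ²(1−α, df) quantile
(α = 0.05 forward, 0.01 backward; df = 1 for occasion/adherence, 2 for
BMI, 3 for caregiver); one best candidate per round (largest ΔOFV,
ties by fewer df then name); a relation survives backward elimination
only if its removal costs more than the backward threshold. A
strict-1df compatibility mode uses the conventional printed constants
3.83/6.64 for every candidate. Forward type-I error is calibrated:
5% ± 3% null inclusion over 200 simulated cohorts (n=100).

Bootstrap: subjects resampled with replacement (occasions travel
together, resamples re-identified), each refit starting from the
original estimates; medians and 90% percentile CIs (type-7 quantiles)
over converged resamples; >50% non-convergence flags the result
unreliable. Coverage of the generating frac_pop is 90% ± 7% over 50
scaled-down replicates (n=100, 200 resamples).

Diagnostics: PRED at η = 0, IPRED at η̂, IWRES = (y − f(η̂))/sd(f(η̂)),
and CWRES by the standard first-order expansion at the conditional
modes: V^(−1/2)(y − f(η̂) + G η̂) with G = ∂f/∂η (central differences,
relative step 1e−5) and V = G Ω Gᵀ + diag(residual variances); matrix
square root by symmetric eigendecomposition, non-PD V floored with a
warning. With Ω inactive CWRES reduces exactly to the scaled residual.
On 10⁴ records simulated at the generating parameters,
|mean(CWRES)| ≤ 0.05 and |SD − 1| ≤ 0.05.

## Synthetic cohorts

`CohortSpec` emulates the study structure: n=50 (default; recovery
experiments use n=500), two occasions (day 0 and 90), categorical
covariates at the published frequencies (BMI normal/thin/overweight
54/30/15%, caregiver grandparent/parent/uncle-aunt/sibling
40/20/30/10%, 54% female), adherence VAS ~ N(84.2, 18.1²) truncated to
[30, 100] and shared across occasions (per-occasion redraw is an
option), body weight log-normal (median 50 kg, CV 20%, clipped to
25–90 kg — weight is not published; this is a plausible adolescent
distribution, and it cancels out of frac recovery), and per-analyte
assay ranges (LLOQ 0.05/0.01, ULOQ 20/4 ng/mg; values at or above the
LLOQ are not flagged, and above-range values are not censored).
Negative simulated concentrations are retained before censoring so the
residual model stays unbiased. One generator draw per seed is
byte-reproducible.

What the generator does **not** emulate: hair growth-rate variation and
segmental kinetics; drug–drug interaction terms; adherence
heterogeneity beyond the linear VAS effect. The last point means the
study's observed 18%/12% below-quantification rates — plausibly driven
by episodic non-adherence — are not reproduced under the default hair
link (the simulated rates are a few percent); no conclusion about real
BLQ handling should be drawn from the passing tests.

## Problem sizes and numerical conventions used by the test suite

Recovery: 5 replicate cohorts of 500 subjects × 2 occasions per
analyte, median estimates compared at ±1 percentage point (frac_pop)
and ±0.03 (covariate effects). SCM calibration: 200 null cohorts and
20 effect cohorts at n=100. Bootstrap: 50 × 200 resamples at n=100.
Diagnostics: 10⁴ records. Laplace-vs-quadrature: 20 randomized
IOV-link instances of 5–8 subjects. These sizes keep the full suite at
roughly ten minutes on one CPU.

## Known limitations

- Frac is a scale-confounded ratio: its absolute value is meaningful
  only relative to the internal trough unit.
- ω² components of the plasma side are pass-through constants under
  the default hair link; fitting them requires the point-trough link
  and data that identify them.
- M1 BLQ handling biases low-concentration strata under censoring;
  use M3-style methods if censoring is heavy.
- The Laplace approximation degrades for links with |d ln f/dη| ≫ 1;
  the quadrature oracle bounds that error only up to 2 dimensions.
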