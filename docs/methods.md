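# Methods

`tacppk` implements a two-stage pipeline for predicting tacrolimus
trough concentrations (C0) in adult renal-transplant recipients from
routine therapeutic-drug-monitoring (TDM) data: a population
pharmacokinetic (PPK) stage estimated by FOCE with MAP forecasting, and
a machine-learning stage whose feature set includes the PPK stage's
individual forecasts. Everything runs on synthetic cohorts generated by
the package itself, so every claim the test suite makes is about the
method, not about any particular clinical dataset.

## Population PK model

Structural model: one compartment, first-order absorption and
elimination, oral dosing. Because only pre-dose troughs are observed,
bioavailability F is not identifiable and is absorbed into the apparent
parameters V/F and CL/F; the absorption rate constant is fixed at
ka = 3.86 h⁻¹ (trough-only designs carry no information about
absorption; the fixed value follows the published estimate for this
population — the source table prints 3.86 while the accompanying text
prints 3.84, and we follow the table, which repeats the value
consistently). Predictions superpose the standard one-compartment
absorption term over the dosing history; doses are in mg, V/F in L, and
the mg/L result is scaled ×1000 to ng/mL. When |ka − ke| underflows,
the limiting form (amt/V)·ka·Δt·e^(−ka·Δt) replaces the two-exponential
bracket.

Statistical model: log-normal between-subject variability on V/F and
CL/F (η ~ N(0, diag(ω²_V, ω²_CL)); Table-style "IIV %" is reported as
100·√ω²), and an additive residual on the log scale,
ln C_obs = ln C_pred + ε, ε ~ N(0, σ²). "Residual error (%)" is read as
100·σ, the log-scale SD, which approximates a CV on the natural scale.

Covariate effects are exponential-linear on CL/F, uncentered, matching
the published final equation

    CL/F = 70.6 · e^(−0.348·CYP3A5) · e^(−0.122·HCT)

with CYP3A5 the *3 allele count (0/1/2) and HCT the hematocrit
fraction. Under this convention θ_CL is the CL/F of a hypothetical
HCT = 0 patient; recovery experiments define their targets under the
same convention. Two presets ship: `structural` (covariate-free; 41.1
L/h, 2620 L, ω 73.6 %/31.8 %, σ 37.7 %) and `final` (70.6 L/h, 2560 L,
β as above, ω 65.0 %/23.0 %, σ 35.6 %).

## Estimation (FOCE)

For each subject the conditional mode η̂ of the penalized log-scale
least squares is found by a damped Newton iteration (the exact η-Hessian
of the log-prediction has the closed form m·[[1,−1],[−1,1]] with
m = g″ke² + g′ke, so full Newton steps are available; Gauss-Newton is
the fallback when that Hessian is not positive definite). Gradient
tolerance 10⁻⁶ (scaled up when σ² is numerically tiny, where the
gradient magnitude exceeds float precision), step clamping at |Δη| ≤ 2,
|η| ≤ 8. All subjects iterate simultaneously on padded
patient × observation × dose tensors; the ka-exponential part of the
superposition sum is precomputed once per dataset because ka is fixed.

The marginal likelihood uses the standard FOCE linearization about η̂:
with G the gradient of log-predictions in η, r = y − f(η̂) + Gη̂ and
V = GΩGᵀ + σ²I, each subject contributes
n·ln2π + ln|V| + rᵀV⁻¹r to the objective function value (OFV,
−2·log marginal likelihood on the log-transformed-data scale). No
interaction term is needed because the residual is homoscedastic on the
log scale. V is factored per subject by a batched Cholesky of the full
(≤ 17×17) matrix rather than a 2×2 Woodbury identity: the explicit
factorization is still trivially cheap at these sizes and is immune to
a catastrophic-cancellation failure mode of the low-rank shortcut that,
in extreme parameter regions, fakes an unboundedly negative OFV and
derails the outer optimizer.

Outer optimization runs on log-transformed positive parameters
(covariate β's untransformed): an L-BFGS-B stage with finite-difference
gradients (warm-started inner modes make adjacent evaluations cheap and
the objective effectively smooth), then a Nelder-Mead verification pass
and a final quasi-Newton polish (both skippable via options for
many-fit workflows such as stepwise selection, where the quasi-Newton
stage alone reproduces the full optimum to < 0.01 OFV units in our
checks). Bounds are physiological sanity limits, not tuning: thetas in
[e⁻³, e¹²], log-scale variances ≤ e² (CV far beyond any plausible
trough fit), and each covariate coefficient capped so its effect over
the observed covariate range stays within e^±50. Convergence is
declared on optimizer success or on a flat central-difference OFV
gradient at the returned point; non-convergence returns the best point
found with `converged=False` rather than raising.

Standard errors come from a central-difference Hessian of the OFV on
the natural parameter scale (relative step 10⁻⁴); since OFV = −2 log L,
the covariance is 2·H⁻¹ and RSE% = 100·SE/|estimate|.

MAP ("posthoc") individual estimation reuses the inner solver with the
population parameters fixed; with no usable observations the prior mode
η = 0 is returned and flagged.

## Covariate selection

Greedy forward inclusion / backward elimination on CL/F with
likelihood-ratio thresholds 6.63 (p < 0.01, 1 df) and 7.88 (p < 0.005,
1 df), χ² quantiles rounded to two decimals. One covariate moves per
step with a full refit between steps; ties break by larger OFV change,
then lexicographically, so candidate ordering cannot affect the result.
Threshold comparisons carry a 10⁻⁹ tolerance so the inclusive boundary
convention (a change exactly at the threshold qualifies) survives
floating-point subtraction. A candidate whose fit fails to converge is
skipped with a logged warning. V/F covariates are out of the default
search (only CL/F effects are reported for this drug/population); the
candidate panel defaults to genotype, HCT, weight, labs, sex and
co-medication flags.

## Diagnostics

CWRES standardizes r (as above) by V^(−1/2) (eigendecomposition per
subject); under the generating model they are approximately standard
normal, which the tests check at ≥ 500 observations (mean within ±0.1,
variance in [0.8, 1.2]).

The VPC resimulates the entire design (same doses, times, covariates;
fresh η and ε) — 1000 replicates by default, fewer with a warning below
100 — and compares observed 5th/50th/95th percentiles per
postoperative-day bin against the simulated percentile bands. Binning
uses POD deciles, or one bin per distinct POD when the schedule has few
distinct sampling days; empty bins are merged away. The in-band
fraction (observed points inside the pooled simulated 5th–95th band)
is the calibration summary: ~0.90 expected under the true model on a
fixed-dose design. On a titrated design the VPC over-covers by
construction (~0.95 in our runs): dose adjustment reacts to each
patient's realized concentrations and compresses the observed spread,
while the resimulation keeps the doses fixed — the classic
adaptive-design VPC caveat. The calibration check therefore uses fixed
dosing.

Error metrics follow the conventional definitions: MAE, MAPE%, RMSE,
R² (1 − SSE/SST, guarded to 0 with a warning for constant
observations), plus MPE (signed mean relative error, %, with a
normal-approximation 95% CI) and MRSE% (root mean squared relative
error ×100 — the reading that makes it commensurate with MAPE-scale
errors). Relative metrics reject zero observations.

## Machine-learning stage

One feature row per usable (in-range) trough: weight, current daily
dose (AMT, the sum of administrations in the preceding 24 h — "daily
dose" is our reading of an otherwise ambiguous quantity), POD, labs
(RBC, HCT, DBIL, BUN, CLcr, ALB), CYP3A5 code, three co-medication
flags, UDOSE (cumulative mg/kg since the previous TDM sample; from the
first dose for a patient's first trough), and IPRE — the covariate-free
("basic") PPK model's MAP forecast of the current trough using only
strictly earlier troughs. The one-step-ahead construction prevents the
target from leaking into its own feature; the same-time ("leaky")
variant exists behind a flag for comparison and, as expected, tracks
the target far more closely. Rows with a missing covariate (NaN) are
dropped with a logged count.

Three regressor families: gradient-boosted trees (xgboost), RBF-kernel
ε-SVR and a fully connected feed-forward net (both scikit-learn
pipelines with standardization). Hyperparameters are tuned by a
Tree-structured Parzen Estimator minimizing mean(MAE) + mean(MAPE%)
over patient-grouped inner CV folds — the unit-mixing sum is kept
deliberately, as is conventional for this objective — inside a nested
cross-validation (10 inner / 10 outer folds by default, 100 TPE trials;
tests and the analysis drivers scale these down). Folds are grouped by
patient in both layers because rows within a patient are correlated;
the returned hyperparameters come from a final TPE run on all training
rows, and the outer folds report unbiased metrics of the tuned
pipeline. An SVR search-space oddity in the source material (a
polynomial-kernel "degree" reported for an RBF kernel) is not imitated;
the space tunes C, gamma and epsilon.

The TPE sampler is implemented in-repo (~120 lines): random start-up
(10 trials), good/bad split at the 15% quantile, per-dimension weighted
Parzen densities with a uniform prior component and rank-decaying
kernel weights, 24 candidates scored by the density ratio; categorical
dimensions sample from the Laplace-smoothed good distribution.
Deterministic for a fixed seed.

Feature attribution is additive (Shapley values). For gradient-boosted
trees the path-dependent TreeSHAP algorithm is implemented in float64
over the parsed booster dump (cover-weighted conditional expectations),
so per row the attributions plus the expected value reconstruct the
margin prediction to round-off; routing mirrors the booster's float32
threshold comparisons, and the result agrees with the booster's own
fast float32 implementation to ~10⁻⁵ (which remains the default above
500 rows). SVR/MLP fall back to a seeded Shapley-sampling
approximation over random feature orderings against a background
sample, flagged non-exact.

Per-occasion evaluation groups test predictions by TDM visit number
(1–6, later visits pooled as "7+"). In clinical data the first visit —
before any feedback from measured levels — is typically the hardest to
predict; note that the synthetic generator does not reproduce this
pattern (under protocol titration with a fixed schedule, first-occasion
troughs are still accumulating from uniform weight-based doses and have
the lowest absolute spread), so per-occasion difficulty ordering is a
property of real cohorts that these simulations do not claim.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes:
127 patients by default; CYP3A5 *1/*1 / *1/*3 / *3/*3 at
9.45/33.9/56.7% (whole-cohort frequencies; the printed values sum to
1.0005 and are renormalized); covariates from truncated normal or
moment-matched lognormal marginals (WT 63.3 ± 12.9 kg, HCT
0.29 ± 0.056 as a fraction, RBC 3.06 ± 0.61, DBIL 2.58 ± 1.17, BUN
18.8 ± 10.5, ALB 34.0 ± 3.69; CLcr, not tabulated in the source, uses a
lognormal with mean 55 ± 30 mL/min typical of early post-transplant
function); sex 38% female; co-medication flags at 78.6/99/20.4%
(calcium antagonists / PPI / voriconazole — the training-cohort table
frequencies; the running text gives different usage percentages and the
discrepancy is recorded, not resolved). Small within-patient
day-to-day lab variation (HCT SD 0.015 absolute, 5% relative for other
labs) makes the per-visit covariate panels realistic; the PK engine
summarizes time-varying covariates by their per-patient mean, which is
consistent with generation from a patient-level baseline.

Dosing follows the clinical protocol: 0.1 mg/kg/day split BID (per-dose
amount rounded to 0.5 mg), titrated after each trough toward 10–13
ng/mL in the first month and 5–9 ng/mL thereafter. The titration
multipliers (×0.75 above the window, ×1.25 below, re-rounded) are
protocol details the source does not state; both are configurable.
Troughs are sampled just before a morning dose on a fixed schedule of
16 postoperative days spanning 3–365 (a fixed schedule keeps the TDM
occasion index well defined; the real cohort's POD distribution is
heavily right-skewed, which the schedule approximates only coarsely).
Concentrations are simulated from the PK model with fresh η per patient
and ε per sample; values outside the 2–50 ng/mL assay range are flagged
censored, excluded from estimation and ML targets but kept in the data
model. Co-medication flags have no generative PK effect by default (the
published final model contains none); an optional voriconazole effect
on CL/F exists to probe selection power. Latent η and individual
parameters are recorded per patient for recovery assertions.

What the generator does not emulate: between-covariate correlation,
covariate drift with recovery (e.g., rising HCT), non-adherence,
irregular sampling, or dose-timing deviations. Passing tests therefore
demonstrate that the estimation and ML machinery recovers the truth
under the model's own assumptions at realistic design sizes — not that
the published clinical estimates are correct.

## Problem sizes used by tests and the acceptance script

The simulate-and-refit experiment runs at the study's design size (103
patients × 16 troughs; ~2 min per fit on one core). Experiments that
repeat many fits or many tuning runs use scaled-down designs chosen so
the checked signal stays far from its decision threshold: covariate
selection power/specificity uses 60 patients × 8 troughs over 84 days
(planted-effect ΔOFV ≈ 25–30 against a 6.63 threshold) across 20 seeds
with the quasi-Newton-only fit path; the ML property sweeps use 24–30
patients, 5-fold nested CV and 5 TPE trials; the VPC calibration check
uses 60 patients and 200 replicates.

## Known limitations

* ω²_V is weakly identified from troughs alone (the likelihood is
  nearly flat in η_V at quasi-steady-state troughs); its recovery is
  poor and no claim is made about it. θ_V remains identified through
  the accumulation phase of early troughs.
* The uncentered-HCT convention makes θ_CL and β_HCT strongly
  collinear at small n; the clearance at reference covariates is the
  stable quantity.
* FOCE is an approximation; at two random effects and ≥ 3 observations
  per subject it agrees with adaptive Gauss–Hermite quadrature to
  < 0.5 OFV units in our oracle checks, but no SAEM/importance-sampling
  alternative is provided.
* The residual is homoscedastic on the log scale by construction;
  combined additive+proportional error models are out of scope.
* Selection searches CL/F only by default; V/F covariates were not
  reported for this population and are not searched unless requested.
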