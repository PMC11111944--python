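# tacppk

Population-pharmacokinetic modelling and PK-informed machine learning
for tacrolimus trough-concentration prediction in adult renal-transplant
recipients.

Tacrolimus has a narrow therapeutic window and highly variable
pharmacokinetics; dosing is steered by trough concentrations (C0)
measured at routine therapeutic-drug-monitoring (TDM) visits. This
package implements, end to end, a two-stage prediction pipeline over
such data:

1. **Population PK stage.** A one-compartment oral model with
   first-order absorption (ka fixed at 3.86 h⁻¹) and elimination,
   apparent parameters V/F and CL/F with log-normal between-subject
   variability, and a log-additive residual:

       ln C_obs = ln C_pred + ε,   P_i = TVP · e^(η_i)

   fitted by FOCE (per-subject Laplace-type linearization at the
   conditional η mode). Covariate effects on CL/F are
   exponential-linear; the shipped final model is

       CL/F = 70.6 · e^(−0.348·CYP3A5) · e^(−0.122·HCT)   [L/h]

   with CYP3A5 the *3 allele count (0/1/2) and HCT the hematocrit
   fraction. Stepwise covariate selection (forward ΔOFV ≥ 6.63,
   backward ΔOFV ≥ 7.88), MAP ("posthoc") individual forecasting,
   CWRES diagnostics and visual predictive checks are included.

2. **Machine-learning stage.** Gradient-boosted trees, RBF-SVR and a
   feed-forward net predict the next trough from clinical covariates,
   dosing features (daily dose; UDOSE, the cumulative mg/kg since the
   previous sample) and — crucially — IPRE, the covariate-free PK
   model's one-step-ahead MAP forecast. Hyperparameters are tuned by a
   Tree-structured Parzen Estimator inside nested, patient-grouped
   cross-validation; predictions are explained by exact additive
   attribution (float64 TreeSHAP for tree models).

No clinical dataset ships with the package: a synthetic-cohort
generator (`tacppk.simulate`) reproduces the cohort structure —
genotype frequencies, covariate marginals, protocol dosing with
titration, assay censoring at 2–50 ng/mL — with known ground truth, so
every stage is testable. See `docs/methods.md` for the full model
description and design choices.

## Worked example

```python
from tacppk import (CohortConfig, generate_cohort, split_train_test,
                    structural_preset, final_preset, typical_clearance)
from tacppk.estimation import fit_population

# a 40-patient synthetic cohort, ~16 troughs each, known truth
records = generate_cohort(CohortConfig(n_patients=40, seed=3))
fit = fit_population(records, final_preset(), options={"compute_rse": False})
e = fit.estimates
print(f"CL/F {e.theta_cl:.1f} L/h, V/F {e.theta_v:.0f} L, "
      f"beta_CYP3A5 {e.covariates['cyp3a5_code']:.3f}, "
      f"IIV CL/F {fit.iiv_cv_pct['cl_f']:.1f}%, residual {fit.residual_sd_pct:.1f}%")
print(f"CYP3A5 *3/*3 vs *1/*1 clearance ratio: "
      f"{typical_clearance(e, cyp3a5_code=2, hct=0.29) / typical_clearance(e, cyp3a5_code=0, hct=0.29):.3f}")
```

prints (seed 3):

```
CL/F 72.5 L/h, V/F 2766 L, beta_CYP3A5 -0.291, IIV CL/F 22.2%, residual 37.2%
CYP3A5 *3/*3 vs *1/*1 clearance ratio: 0.559
```

i.e. at this cohort size the refit recovers the generating typical
clearance (70.6 L/h) within a few percent, the CL/F inter-individual
variability (23%) and residual error (35.6%) closely, and a genotype
effect of the right size — a *3/*3 patient clears roughly half as fast
as a *1/*1 patient, which is why expressers need substantially higher
doses for the same trough.

## Analysis drivers

Numbered scripts under `analysis/` run the full study on a synthetic
cohort and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # cohort + ground truth
python analysis/02_fit_ppk.py            # basic + final FOCE fits
python analysis/03_select_covariates.py  # stepwise LRT selection
python analysis/04_diagnostics_vpc.py    # CWRES, VPC, MAP test metrics
python analysis/05_ml_stack.py           # nested-CV ML + attribution
```

The same pipeline is scriptable via the `tacppk` CLI
(`tacppk simulate | convert | split | fit | select | vpc | ml | all`).

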