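#!/usr/bin/env python
"""Split the cohort by patient and fit the population-PK models by FOCE.

Fits the covariate-free (basic) model and the final covariate model
(CYP3A5 allele count and hematocrit on CL/F) to the training patients,
prints a parameter table with RSE%, and writes both fits as JSON.
Run 01_simulate_cohort.py first.
"""

import json
import sys
from pathlib import Path


from tacppk import final_preset, read_event_table, split_train_test, structural_preset
from tacppk.estimation import fit_population
from tacppk.pipeline import fit_to_dict

OUT = Path("results")
SEED = 7


def report(tag, fit):
    e = fit.estimates
    rows = [("V/F (L)", e.theta_v, "theta_v"), ("CL/F (L/h)", e.theta_cl, "theta_cl")]
    for name, beta in e.covariates.items():
        rows.append((f"{name} on CL/F", beta, f"beta_{name}"))
    rows += [
        ("IIV V/F (CV%)", fit.iiv_cv_pct["v_f"], "omega2_v"),
        ("IIV CL/F (CV%)", fit.iiv_cv_pct["cl_f"], "omega2_cl"),
        ("residual SD (%)", fit.residual_sd_pct, "sigma2"),
    ]
    print(f"\n{tag}: OFV {fit.ofv:.2f}, converged={fit.converged}")
    print(f"  {'parameter':<22}{'estimate':>12}{'RSE%':>8}")
    for label, value, key in rows:
        rse = fit.rse_pct.get(key, float('nan'))
        print(f"  {label:<22}{value:>12.3f}{rse:>8.1f}")


def main() -> None:
    records = read_event_table(OUT / "events.csv")
    train, test = split_train_test(records, 0.8, seed=SEED)
    print(f"{len(train)} training / {len(test)} test patients")

    basic = fit_population(train, structural_preset())
    report("basic (covariate-free) model", basic)
    (OUT / "fit_basic.json").write_text(
        json.dumps(fit_to_dict(basic), indent=1, default=float)
    )

    final = fit_population(train, final_preset())
    report("final covariate model", final)
    (OUT / "fit_final.json").write_text(
        json.dumps(fit_to_dict(final), indent=1, default=float)
    )
    drop = basic.ofv - final.ofv
    print(f"\nOFV drop from covariates: {drop:.2f}")


if __name__ == "__main__":
    sys.exit(main())
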