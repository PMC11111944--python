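#!/usr/bin/env python
"""Model diagnostics: goodness of fit, CWRES and visual predictive check.

Loads the final-model fit (from 02), computes conditional weighted
residual summaries, runs a 1000-replicate VPC of the training design,
evaluates one-step-ahead MAP forecasts on the held-out test patients,
and writes the GOF / VPC figures.  Run 01 and 02 first.
"""

import json
import sys
from pathlib import Path

import numpy as np

from tacppk import cwres, prediction_error_report, read_event_table, split_train_test, vpc
from tacppk.diagnostics import gof_plot, vpc_plot
from tacppk.estimation import fit_population
from tacppk.pk_model import final_preset
from tacppk.pipeline import _forecast_map

OUT = Path("results")
SEED = 7


def main() -> None:
    records = read_event_table(OUT / "events.csv")
    train, test = split_train_test(records, 0.8, seed=SEED)
    fit = fit_population(train, final_preset(), options={"compute_rse": False})

    res = np.concatenate(list(cwres(train, fit).values()))
    print(f"CWRES: mean {res.mean():+.3f}, variance {res.var():.3f}, "
          f"|CWRES|>2 in {(np.abs(res) > 2).mean() * 100:.1f}% of points")

    vpc_res = vpc(train, fit.estimates, n_replicates=1000, seed=SEED)
    print(f"VPC: {vpc_res.n_replicates} replicates, observed points inside "
          f"the simulated 5th-95th band: {vpc_res.in_band_fraction * 100:.1f}%")

    obs, pred, _ = _forecast_map(test, fit.estimates)
    report = prediction_error_report(obs, pred)
    print(f"test-set MAP forecasts (n={report.n}): MPE {report.mpe_pct:+.2f}% "
          f"(95% CI {report.mpe_ci[0]:+.2f}, {report.mpe_ci[1]:+.2f}), "
          f"MRSE {report.mrse_pct:.1f}%, MAE {report.mae:.2f} ng/mL")

    gof_plot(train, fit, OUT / "gof.png")
    vpc_plot(vpc_res, train, OUT / "vpc.png")
    (OUT / "map_test_metrics.json").write_text(
        json.dumps(report.as_dict(), indent=1)
    )
    print(f"wrote {OUT/'gof.png'}, {OUT/'vpc.png'}, {OUT/'map_test_metrics.json'}")


if __name__ == "__main__":
    sys.exit(main())
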