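#!/usr/bin/env python
"""PK-informed machine learning: tune, evaluate and explain.

Builds the feature table (clinical covariates + UDOSE + one-step-ahead
IPRE from the basic PK model), tunes gradient-boosted trees, SVR and an
MLP by nested cross-validated TPE (trials reduced from the method's 100
to keep the run short; pass --trials to change), compares them against
the MAP forecasts of the basic and final PK models on the test
patients, and prints the attribution ranking of the best model.
Run 01 first.
"""

import argparse
import json
import sys
from pathlib import Path

from tacppk import (
    build_feature_table,
    feature_attribution,
    fit_final_and_predict,
    per_occasion_errors,
    read_event_table,
    split_train_test,
    tune_nested_cv,
)
from tacppk.estimation import fit_population
from tacppk.ml import _feature_columns, make_estimator
from tacppk.pipeline import _forecast_map
from tacppk.pk_model import final_preset, structural_preset
from tacppk.diagnostics import prediction_error_report

OUT = Path("results")
SEED = 7


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--trials", type=int, default=10)
    parser.add_argument("--folds", type=int, default=3)
    args = parser.parse_args()

    records = read_event_table(OUT / "events.csv")
    train, test = split_train_test(records, 0.8, seed=SEED)
    basic = fit_population(train, structural_preset(), options={"compute_rse": False})
    final = fit_population(train, final_preset(), options={"compute_rse": False})
    rows_train = build_feature_table(train, basic)
    rows_test = build_feature_table(test, basic)
    print(f"feature table: {len(rows_train)} train / {len(rows_test)} test rows")

    comparison = {}
    for tag, model in (("ppk_basic", basic), ("ppk_final", final)):
        obs, pred, _ = _forecast_map(test, model.estimates)
        comparison[tag] = prediction_error_report(obs, pred)

    best = None
    for algo in ("xgb", "svr", "mlp"):
        tuned = tune_nested_cv(
            rows_train, algo, n_trials=args.trials, seed=SEED,
            inner_folds=args.folds, outer_folds=args.folds,
        )
        pred, report = fit_final_and_predict(rows_train, rows_test, tuned)
        comparison[algo] = report
        if best is None or report.mae < comparison[best[0]].mae:
            best = (algo, tuned, pred)

    print(f"\n{'model':<12}{'MAE':>7}{'MAPE%':>8}{'RMSE':>7}{'R2':>7}")
    for tag, rep in comparison.items():
        print(f"{tag:<12}{rep.mae:>7.2f}{rep.mape_pct:>8.1f}{rep.rmse:>7.2f}{rep.r2:>7.2f}")

    algo, tuned, pred = best
    print(f"\nbest model: {algo}; per-occasion error on test patients:")
    for occ, rep in per_occasion_errors(pred, rows_test).items():
        print(f"  occasion {occ:<3} n={rep.n:<4} MPE {rep.mpe_pct:+6.1f}%  MAE {rep.mae:.2f}")

    est = make_estimator(algo, tuned.hyperparameters, seed=tuned.seed)
    est.fit(
        rows_train[_feature_columns(rows_train)].to_numpy(float),
        rows_train["target"].to_numpy(float),
    )
    att = feature_attribution(est, rows_train, seed=SEED)
    print(f"\nattribution ranking ({'exact' if att.exact else 'sampled'}):")
    print(att.ranking.head(6).to_string(index=False))

    (OUT / "ml_comparison.json").write_text(
        json.dumps({k: v.as_dict() for k, v in comparison.items()}, indent=1)
    )
    print(f"\nwrote {OUT/'ml_comparison.json'}")


if __name__ == "__main__":
    sys.exit(main())
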