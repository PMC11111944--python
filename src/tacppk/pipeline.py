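"""End-to-end pipeline: simulate -> split -> fit -> select -> VPC -> ML.

``run_paper_pipeline`` executes the whole analysis on a synthetic
cohort and writes machine-readable JSON artifacts plus a Markdown
summary, including a comparison table of the MAP forecasts (basic and
final PK model) against each tuned machine-learning model on the test
patients.  All stages are reproducible from (config, seed); any stage
failure halts the pipeline with the stage name while earlier artifacts
remain on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diagnostics import prediction_error_report, vpc
from .estimation import FitResult, fit_population
from .io import split_train_test, write_event_table
from .ml import (
    build_feature_table,
    fit_final_and_predict,
    per_occasion_errors,
    tune_nested_cv,
)
from .attribution import feature_attribution
from .pk_model import PopulationModel, structural_preset
from .selection import DEFAULT_CANDIDATES, stepwise_selection
from .simulate import CohortConfig, generate_cohort
from . import ml as ml_mod

__all__ = ["PipelineConfig", "PipelineError", "run_paper_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 7
    n_patients: int = 127
    train_fraction: float = 0.8
    forward_threshold: float = 6.63
    backward_threshold: float = 7.88
    n_sim: int = 1000
    inner_folds: int = 10
    outer_folds: int = 10
    tpe_trials: int = 100
    algorithms: tuple = ("xgb", "svr", "mlp")
    #: candidate covariates searched; the full panel by default
    candidates: tuple = DEFAULT_CANDIDATES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    fit_options: dict | None = None


def _model_dict(model: PopulationModel) -> dict:
    return {
        "ka": model.ka,
        "theta_v": model.theta_v,
        "theta_cl": model.theta_cl,
        "covariates": dict(model.covariates),
        "omega2_v": model.omega2_v,
        "omega2_cl": model.omega2_cl,
        "sigma2": model.sigma2,
    }


def fit_to_dict(fit: FitResult) -> dict:
    return {
        "estimates": _model_dict(fit.estimates),
        "rse_pct": fit.rse_pct,
        "ofv": fit.ofv,
        "converged": fit.converged,
        "iiv_cv_pct": fit.iiv_cv_pct,
        "residual_sd_pct": fit.residual_sd_pct,
        "ebes": {
            pid: {"eta_v": p.eta_v, "eta_cl": p.eta_cl, "v_f": p.v_f, "cl_f": p.cl_f}
            for pid, p in fit.ebes.items()
        },
    }


def _forecast_map(records, model) -> tuple[np.ndarray, np.ndarray, "object"]:
    """One-step-ahead MAP trough forecasts for a cohort (obs, pred, rows)."""
    import pandas as pd

    obs_all, pred_all, occ_all, pid_all = [], [], [], []
    for rec in records:
        usable = rec.usable_observations
        if not usable:
            continue
        ipre = ml_mod._sequential_ipre(rec, model)
        obs_all += [o.conc for o in usable]
        occ_all += [o.occasion_index for o in usable]
        pid_all += [rec.patient_id] * len(usable)
        pred_all += list(ipre)
    rows = pd.DataFrame(
        {
            "patient_id": pid_all,
            "occasion_index": occ_all,
            "target": obs_all,
        }
    )
    return np.array(obs_all), np.array(pred_all), rows


def run_paper_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": {"seed": config.seed, "n_patients": config.n_patients}}
    t_start = time.time()

    def _stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t_start)

    # -- simulate ------------------------------------------------------------
    stage = "simulate"
    try:
        _stage(stage)
        cohort_cfg = dataclasses.replace(
            config.cohort, n_patients=config.n_patients, seed=config.seed
        )
        records = generate_cohort(cohort_cfg)
        write_event_table(records, outdir / "events.csv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- split ---------------------------------------------------------------
    stage = "split"
    try:
        _stage(stage)
        train, test = split_train_test(records, config.train_fraction, config.seed)
        bundle["split"] = {
            "n_train": len(train),
            "n_test": len(test),
            "seed": config.seed,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    fit_opts = config.fit_options

    # -- fit basic model -----------------------------------------------------
    stage = "fit_basic"
    try:
        _stage(stage)
        basic_fit = fit_population(train, structural_preset(), options=fit_opts)
        bundle["fit_basic"] = fit_to_dict(basic_fit)
        (outdir / "fit_basic.json").write_text(
            json.dumps(bundle["fit_basic"], indent=1, default=float)
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- covariate selection -> final model ----------------------------------
    stage = "select"
    try:
        _stage(stage)
        trace = stepwise_selection(
            train,
            basic_fit.estimates,
            config.candidates,
            config.forward_threshold,
            config.backward_threshold,
            fit_options=fit_opts,
        )
        bundle["selection"] = {
            "steps": [dataclasses.asdict(s) for s in trace.steps],
            "retained": trace.retained,
        }
        (outdir / "trace.json").write_text(
            json.dumps(bundle["selection"], indent=1, default=float)
        )
        final_fit = trace.final_fit
        bundle["fit_final"] = fit_to_dict(final_fit)
        (outdir / "fit_final.json").write_text(
            json.dumps(bundle["fit_final"], indent=1, default=float)
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- VPC -----------------------------------------------------------------
    stage = "vpc"
    try:
        if config.n_sim > 0:
            _stage(stage)
            vpc_res = vpc(
                train, final_fit.estimates, n_replicates=config.n_sim, seed=config.seed
            )
            bundle["vpc"] = {
                "n_replicates": vpc_res.n_replicates,
                "in_band_fraction": vpc_res.in_band_fraction,
                "bin_edges": vpc_res.bin_edges.tolist(),
                "observed_pct": vpc_res.observed_pct.tolist(),
                "sim_pct_median": vpc_res.sim_pct_median.tolist(),
            }
            (outdir / "vpc.json").write_text(
                json.dumps(bundle["vpc"], indent=1, default=float)
            )
        else:
            logger.info("n_sim=0: VPC stage skipped")
            bundle["vpc"] = None
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- MAP forecasting comparison rows ------------------------------------
    stage = "map_forecast"
    comparison: dict[str, dict] = {}
    try:
        _stage(stage)
        obs_b, pred_b, _ = _forecast_map(test, basic_fit.estimates)
        comparison["ppk_basic"] = prediction_error_report(obs_b, pred_b).as_dict()
        obs_f, pred_f, _ = _forecast_map(test, final_fit.estimates)
        comparison["ppk_final"] = prediction_error_report(obs_f, pred_f).as_dict()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- ML stage ------------------------------------------------------------
    stage = "ml"
    try:
        _stage(stage)
        rows_train = build_feature_table(train, basic_fit)
        rows_test = build_feature_table(test, basic_fit)
        bundle["ml"] = {}
        for algo in config.algorithms:
            tuned = tune_nested_cv(
                rows_train,
                algo,
                n_trials=config.tpe_trials,
                seed=config.seed,
                inner_folds=config.inner_folds,
                outer_folds=config.outer_folds,
            )
            pred, report = fit_final_and_predict(rows_train, rows_test, tuned)
            occasions = per_occasion_errors(pred, rows_test)
            est = ml_mod.make_estimator(algo, tuned.hyperparameters, seed=tuned.seed)
            est.fit(
                rows_train[ml_mod._feature_columns(rows_train)].to_numpy(float),
                rows_train["target"].to_numpy(float),
            )
            attribution = feature_attribution(est, rows_train, seed=config.seed)
            entry = {
                "hyperparameters": tuned.hyperparameters,
                "inner_cv_score": tuned.inner_cv_score,
                "outer_cv_mae": tuned.outer_mae,
                "test_metrics": report.as_dict(),
                "per_occasion": {k: v.as_dict() for k, v in occasions.items()},
                "attribution_ranking": attribution.ranking.to_dict("records"),
                "attribution_exact": attribution.exact,
            }
            bundle["ml"][algo] = entry
            (outdir / f"ml_{algo}.json").write_text(
                json.dumps(entry, indent=1, default=float)
            )
            comparison[algo] = report.as_dict()
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # -- comparison table ----------------------------------------------------
    stage = "report"
    try:
        _stage(stage)
        bundle["comparison"] = comparison
        (outdir / "comparison.json").write_text(
            json.dumps(comparison, indent=1, default=float)
        )
        lines = [
            "# Pipeline summary",
            "",
            f"- patients: {config.n_patients} (train {bundle['split']['n_train']}, "
            f"test {bundle['split']['n_test']}); seed {config.seed}",
            f"- retained covariates: {', '.join(bundle['selection']['retained']) or 'none'}",
            "",
            "| model | MAE | MAPE % | RMSE | R2 |",
            "|---|---|---|---|---|",
        ]
        for name, m in comparison.items():
            lines.append(
                f"| {name} | {m['mae']:.2f} | {m['mape_pct']:.1f} | "
                f"{m['rmse']:.2f} | {m['r2']:.2f} |"
            )
        (outdir / "summary.md").write_text("\n".join(lines) + "\n")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return bundle
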