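"""PK-informed machine-learning stage.

The feature table couples routine clinical covariates with two
PK-derived quantities: UDOSE (cumulative dose per kg since the previous
trough sample) and IPRE, the covariate-free ("basic") population-PK
model's individual prediction of the current trough.  IPRE is produced
by MAP forecasting using only the troughs strictly before the current
one — a one-step-ahead forecast — so the target never leaks into its
own feature; the same-time (leaky) variant is available behind a flag
for comparison.

Three regressor families are supported: gradient-boosted trees
(xgboost), epsilon-SVR with an RBF kernel, and a fully connected
feed-forward net.  Hyperparameters are tuned by a Tree-structured
Parzen Estimator minimizing mean(MAE) + mean(MAPE%) over inner
cross-validation folds (the unit-mixing sum is kept deliberately, as is
conventional for this objective), inside a nested cross-validation
whose folds are grouped by patient in both layers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import PatientRecord
from .diagnostics import PredictionErrorReport, prediction_error_report
from .estimation import (
    FitResult,
    _individual_params,
    _log_predictions,
    _solve_inner,
    compile_dataset,
)
from .pk_model import PopulationModel
from . import tpe

__all__ = [
    "FEATURE_COLUMNS",
    "TunedModel",
    "build_feature_table",
    "default_search_space",
    "make_estimator",
    "tune_nested_cv",
    "fit_final_and_predict",
    "per_occasion_errors",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "wt",
    "amt",
    "pod",
    "rbc",
    "hct",
    "dbil",
    "bun",
    "clcr",
    "alb",
    "cyp3a5_code",
    "comed_ca_antagonist",
    "comed_ppi",
    "comed_voriconazole",
    "udose",
    "ipre",
]


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def _sequential_ipre(
    record: PatientRecord, model: PopulationModel, leaky: bool = False
) -> np.ndarray:
    """One-step-ahead MAP prediction at each usable observation time.

    For the k-th usable trough the empirical-Bayes etas are estimated
    from troughs 1..k-1 only (all troughs up to and including k when
    ``leaky``), then the model predicts at the k-th time.
    """
    data = compile_dataset([record], list(model.covariates), ka=model.ka)
    n_o = int(data.n_obs[0])
    full_mask = data.obs_mask.copy()
    ipre = np.empty(n_o)
    eta = np.zeros((1, 2))
    for k in range(n_o):
        cut = k + 1 if leaky else k
        mask = full_mask.copy()
        mask[0, cut:] = False
        sub = dataclasses.replace(data, obs_mask=mask, n_obs=mask.sum(axis=1))
        eta = _solve_inner(sub, model, eta)
        v, cl = _individual_params(data, model, eta)
        f, _, _ = _log_predictions(data, v, cl)
        ipre[k] = np.exp(f[0, k])
    return ipre


def build_feature_table(
    records: Sequence[PatientRecord],
    basic_fit: "FitResult | PopulationModel",
    leaky: bool = False,
) -> pd.DataFrame:
    """One row per usable trough: covariates, dosing features, IPRE, target.

    UDOSE is the total dose (mg) administered in the interval since the
    previous TDM sample (from the first dose, for a patient's first
    trough) divided by the current body weight.  AMT is the current
    daily dose (sum of administrations in the 24 h up to the trough).
    Rows with a missing covariate are dropped, with a logged count.
    """
    model = basic_fit.estimates if isinstance(basic_fit, FitResult) else basic_fit
    rows: list[dict] = []
    for rec in records:
        usable = rec.usable_observations
        if not usable:
            continue
        ipre = _sequential_ipre(rec, model, leaky=leaky)
        dose_times = np.array([d.time for d in rec.doses])
        dose_amts = np.array([d.amount for d in rec.doses])
        all_times = [o.time for o in rec.observations]
        for k, obs in enumerate(usable):
            panel = rec.panel_for_observation(rec.observations.index(obs))
            prior_times = [t for t in all_times if t < obs.time]
            t_prev = max(prior_times) if prior_times else 0.0
            in_window = (dose_times > t_prev) & (dose_times <= obs.time)
            if not prior_times:
                in_window = dose_times <= obs.time
            udose = float(dose_amts[in_window].sum()) / panel.wt
            daily = (dose_times > obs.time - 24.0) & (dose_times <= obs.time)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "occasion_index": obs.occasion_index,
                    "wt": panel.wt,
                    "amt": float(dose_amts[daily].sum()),
                    "pod": obs.pod,
                    "rbc": panel.rbc,
                    "hct": panel.hct,
                    "dbil": panel.dbil,
                    "bun": panel.bun,
                    "clcr": panel.clcr,
                    "alb": panel.alb,
                    "cyp3a5_code": panel.cyp3a5_code,
                    "comed_ca_antagonist": panel.comed_ca_antagonist,
                    "comed_ppi": panel.comed_ppi,
                    "comed_voriconazole": panel.comed_voriconazole,
                    "udose": udose,
                    "ipre": float(ipre[k]),
                    "target": obs.conc,
                }
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    complete = frame.dropna()
    dropped = len(frame) - len(complete)
    if dropped:
        logger.info("dropped %d row(s) with missing covariates", dropped)
    return complete.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Estimators and search spaces
# ---------------------------------------------------------------------------

def default_search_space(algorithm: str) -> dict:
    """Hyperparameter search spaces bracketing typical optima for
    trough-prediction problems of a few thousand rows."""
    if algorithm == "xgb":
        return {
            "n_estimators": tpe.Int(50, 400, log=True),
            "max_depth": tpe.Int(3, 10),
            "learning_rate": tpe.Float(0.01, 0.3, log=True),
            "subsample": tpe.Float(0.5, 1.0),
            "colsample_bytree": tpe.Float(0.5, 1.0),
            "min_child_weight": tpe.Float(0.5, 10.0, log=True),
            "reg_lambda": tpe.Float(1e-2, 10.0, log=True),
            "gamma": tpe.Float(0.0, 5.0),
        }
    if algorithm == "svr":
        return {
            "C": tpe.Float(0.1, 100.0, log=True),
            "gamma": tpe.Float(1e-3, 1.0, log=True),
            "epsilon": tpe.Float(0.01, 1.0, log=True),
        }
    if algorithm == "mlp":
        return {
            "n_layers": tpe.Int(1, 3),
            "units1": tpe.Int(16, 256, log=True),
            "units2": tpe.Int(16, 256, log=True),
            "units3": tpe.Int(16, 256, log=True),
            "alpha": tpe.Float(1e-5, 1e-1, log=True),
            "learning_rate_init": tpe.Float(1e-5, 1e-2, log=True),
        }
    raise ValueError(f"unknown algorithm {algorithm!r}; expected xgb, svr or mlp")


def default_hyperparameters(algorithm: str) -> dict:
    if algorithm == "xgb":
        return {
            "n_estimators": 150,
            "max_depth": 5,
            "learning_rate": 0.1,
            "subsample": 0.9,
            "colsample_bytree": 0.9,
            "min_child_weight": 1.0,
            "reg_lambda": 1.0,
            "gamma": 0.0,
        }
    if algorithm == "svr":
        return {"C": 10.0, "gamma": 0.05, "epsilon": 0.1}
    if algorithm == "mlp":
        return {
            "n_layers": 2,
            "units1": 64,
            "units2": 64,
            "units3": 32,
            "alpha": 1e-3,
            "learning_rate_init": 1e-3,
        }
    raise ValueError(f"unknown algorithm {algorithm!r}")


def make_estimator(algorithm: str, params: dict, seed: int = 0):
    """Instantiate the (pipeline) estimator for one algorithm family."""
    if algorithm == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=int(params["n_estimators"]),
            max_depth=int(params["max_depth"]),
            learning_rate=float(params["learning_rate"]),
            subsample=float(params["subsample"]),
            colsample_bytree=float(params["colsample_bytree"]),
            min_child_weight=float(params["min_child_weight"]),
            reg_lambda=float(params["reg_lambda"]),
            gamma=float(params["gamma"]),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if algorithm == "svr":
        from sklearn.svm import SVR

        return make_pipeline(
            StandardScaler(),
            SVR(
                kernel="rbf",
                C=float(params["C"]),
                gamma=float(params["gamma"]),
                epsilon=float(params["epsilon"]),
            ),
        )
    if algorithm == "mlp":
        from sklearn.neural_network import MLPRegressor

        layers = tuple(
            int(params[f"units{i + 1}"]) for i in range(int(params["n_layers"]))
        )
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=layers,
                alpha=float(params["alpha"]),
                learning_rate_init=float(params["learning_rate_init"]),
                max_iter=500,
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Nested cross-validation with TPE tuning
# ---------------------------------------------------------------------------

def _feature_columns(rows: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_COLUMNS if c in rows.columns]


def _group_folds(
    patient_ids: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Row-index folds with whole patients per fold (no leakage)."""
    unique = np.array(sorted(set(patient_ids)))
    if len(unique) < k:
        raise ValueError(f"need >= {k} patients for {k}-fold grouping, got {len(unique)}")
    perm = rng.permutation(unique)
    groups = np.array_split(perm, k)
    folds = []
    for grp in groups:
        members = set(grp)
        folds.append(np.flatnonzero([pid in members for pid in patient_ids]))
    return folds


def _cv_objective(
    rows: pd.DataFrame, algorithm: str, params: dict, folds: list[np.ndarray], seed: int
) -> float:
    """mean(MAE) + mean(MAPE%) over CV folds — the TPE tuning objective."""
    features = _feature_columns(rows)
    X = rows[features].to_numpy(dtype=float)
    y = rows["target"].to_numpy(dtype=float)
    maes, mapes = [], []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(rows)), test_idx)
        est = make_estimator(algorithm, params, seed=seed)
        try:
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
        except Exception:
            return np.inf
        rel = np.abs(pred - y[test_idx]) / y[test_idx]
        maes.append(float(np.mean(np.abs(pred - y[test_idx]))))
        mapes.append(float(np.mean(rel) * 100.0))
    return float(np.mean(maes) + np.mean(mapes))


@dataclass
class TunedModel:
    """Outcome of nested-CV TPE tuning for one algorithm family."""

    algorithm: str
    hyperparameters: dict
    inner_cv_score: float
    outer_cv_metrics: list[PredictionErrorReport]
    outer_predictions: pd.DataFrame
    seed: int = 0

    @property
    def outer_mae(self) -> float:
        return float(np.mean([m.mae for m in self.outer_cv_metrics]))


def tune_nested_cv(
    rows: pd.DataFrame,
    algorithm: str,
    space: dict | None = None,
    n_trials: int = 100,
    seed: int = 0,
    inner_folds: int = 10,
    outer_folds: int = 10,
) -> TunedModel:
    """Nested cross-validation: an inner patient-grouped CV drives the
    TPE search, an outer patient-grouped CV reports unbiased metrics of
    the tuned pipeline; the returned hyperparameters come from a final
    TPE run on all rows.  Deterministic for fixed seed."""
    if rows.empty:
        raise ValueError("empty feature table")
    space = space or default_search_space(algorithm)
    if not space:
        raise ValueError("empty search space")
    ids = rows["patient_id"].to_numpy()
    seeds = np.random.SeedSequence(seed).spawn(outer_folds + 2)
    rng_outer = np.random.default_rng(seeds[0])
    outer = _group_folds(ids, outer_folds, rng_outer)
    features = _feature_columns(rows)
    X = rows[features].to_numpy(dtype=float)
    y = rows["target"].to_numpy(dtype=float)
    outer_metrics: list[PredictionErrorReport] = []
    outer_pred_frames = []
    for fold_i, test_idx in enumerate(outer):
        train_idx = np.setdiff1d(np.arange(len(rows)), test_idx)
        train_rows = rows.iloc[train_idx].reset_index(drop=True)
        fold_seed = int(seeds[fold_i + 1].generate_state(1)[0] % 2**31)
        rng_inner = np.random.default_rng(fold_seed)
        inner = _group_folds(
            train_rows["patient_id"].to_numpy(),
            min(inner_folds, train_rows["patient_id"].nunique()),
            rng_inner,
        )
        best_params, _, _ = tpe.minimize(
            lambda p: _cv_objective(train_rows, algorithm, p, inner, fold_seed),
            space,
            n_trials=n_trials,
            seed=fold_seed,
        )
        est = make_estimator(algorithm, best_params, seed=fold_seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        outer_metrics.append(prediction_error_report(y[test_idx], pred))
        outer_pred_frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids[test_idx],
                    "occasion_index": rows["occasion_index"].to_numpy()[test_idx],
                    "target": y[test_idx],
                    "pred": pred,
                    "fold": fold_i,
                }
            )
        )
    final_seed = int(seeds[-1].generate_state(1)[0] % 2**31)
    rng_final = np.random.default_rng(final_seed)
    inner_all = _group_folds(
        ids, min(inner_folds, rows["patient_id"].nunique()), rng_final
    )
    best_params, best_score, _ = tpe.minimize(
        lambda p: _cv_objective(rows, algorithm, p, inner_all, final_seed),
        space,
        n_trials=n_trials,
        seed=final_seed,
    )
    return TunedModel(
        algorithm=algorithm,
        hyperparameters=best_params,
        inner_cv_score=float(best_score),
        outer_cv_metrics=outer_metrics,
        outer_predictions=pd.concat(outer_pred_frames, ignore_index=True),
        seed=final_seed,
    )


def fit_final_and_predict(
    rows_train: pd.DataFrame,
    rows_test: pd.DataFrame,
    tuned: TunedModel,
) -> tuple[np.ndarray, PredictionErrorReport]:
    """Refit the tuned pipeline on all training rows and evaluate on the
    held-out test rows (patients must be disjoint)."""
    shared = set(rows_train["patient_id"]) & set(rows_test["patient_id"])
    if shared:
        raise ValueError(f"train and test share patient(s): {sorted(shared)[:5]}")
    cols_train = _feature_columns(rows_train)
    cols_test = _feature_columns(rows_test)
    if cols_train != cols_test:
        diff = sorted(set(cols_train) ^ set(cols_test))
        raise ValueError(f"feature-schema mismatch between train and test: {diff}")
    est = make_estimator(tuned.algorithm, tuned.hyperparameters, seed=tuned.seed)
    est.fit(
        rows_train[cols_train].to_numpy(dtype=float),
        rows_train["target"].to_numpy(dtype=float),
    )
    pred = est.predict(rows_test[cols_test].to_numpy(dtype=float))
    report = prediction_error_report(rows_test["target"].to_numpy(dtype=float), pred)
    return np.asarray(pred, dtype=float), report


def per_occasion_errors(
    predictions: np.ndarray, rows: pd.DataFrame, max_occasion: int = 6
) -> dict[str, PredictionErrorReport]:
    """Error metrics grouped by TDM occasion (1..6; later visits pooled
    under "7+"); empty groups are omitted."""
    predictions = np.asarray(predictions, dtype=float)
    if len(predictions) != len(rows):
        raise ValueError("predictions and rows length mismatch")
    occ = rows["occasion_index"].to_numpy()
    y = rows["target"].to_numpy(dtype=float)
    out: dict[str, PredictionErrorReport] = {}
    for i in range(1, max_occasion + 1):
        sel = occ == i
        if sel.any():
            out[str(i)] = prediction_error_report(y[sel], predictions[sel])
    sel = occ > max_occasion
    if sel.any():
        out[f"{max_occasion + 1}+"] = prediction_error_report(y[sel], predictions[sel])
    return out
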