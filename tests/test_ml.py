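"""Feature assembly, nested-CV tuning, attribution and occasion errors."""

import numpy as np
import pandas as pd
import pytest

from tacppk import (
    DosingEvent,
    PatientRecord,
    TroughObservation,
    build_feature_table,
    feature_attribution,
    fit_final_and_predict,
    per_occasion_errors,
    tune_nested_cv,
)
from tacppk.attribution import AttributionResult
from tacppk.ml import (
    TunedModel,
    _feature_columns,
    _group_folds,
    default_hyperparameters,
    make_estimator,
)
from tacppk.pk_model import structural_preset
from tacppk.simulate import generate_cohort

from conftest import make_panel, short_config


def default_tuned(algorithm="xgb", **overrides) -> TunedModel:
    params = default_hyperparameters(algorithm)
    params.update(overrides)
    return TunedModel(
        algorithm=algorithm, hyperparameters=params, inner_cv_score=np.nan,
        outer_cv_metrics=[], outer_predictions=pd.DataFrame(), seed=0,
    )


@pytest.fixture(scope="module")
def feature_rows():
    records = generate_cohort(short_config(n_patients=24, seed=51))
    return build_feature_table(records, structural_preset())


class TestBuildFeatureTable:
    def test_udose_hand_arithmetic(self):
        # 5 mg BID for exactly 3 days between two troughs, 60 kg
        doses = [DosingEvent(12.0 * i, 5.0) for i in range(20)]
        obs = [
            TroughObservation(time=96.0, conc=6.0, pod=4.0, occasion_index=1),
            TroughObservation(time=168.0, conc=7.0, pod=7.0, occasion_index=2),
        ]
        rec = PatientRecord("U1", doses, obs, [make_panel(wt=60.0)] * 2)
        rows = build_feature_table([rec], structural_preset())
        # (96, 168] h contains 6 doses of 5 mg -> 30 mg / 60 kg
        assert rows.loc[1, "udose"] == pytest.approx(0.5)

    def test_first_trough_spans_from_first_dose(self):
        doses = [DosingEvent(12.0 * i, 4.0) for i in range(10)]
        obs = [TroughObservation(time=96.0, conc=6.0, pod=4.0, occasion_index=1)]
        rec = PatientRecord("U2", doses, obs, [make_panel(wt=80.0)])
        rows = build_feature_table([rec], structural_preset())
        # doses at t=0..96 inclusive: 9 doses in (.., 96] plus t=0 -> 9*4
        in_window = sum(4.0 for d in doses if d.time <= 96.0)
        assert rows.loc[0, "udose"] == pytest.approx(in_window / 80.0)

    def test_missing_covariate_row_dropped(self):
        records = generate_cohort(short_config(n_patients=2, seed=52))
        rec = records[0]
        panels = list(rec.covariates)
        panels[2] = make_panel(hct=float("nan"))
        broken = PatientRecord(rec.patient_id, rec.doses, rec.observations, panels)
        rows = build_feature_table([broken, records[1]], structural_preset())
        n_expected = (
            len(broken.usable_observations)
            + len(records[1].usable_observations)
            - (1 if not broken.observations[2].censored else 0)
        )
        assert len(rows) == n_expected

    def test_ipre_positive_and_daily_dose_bid(self, feature_rows):
        assert (feature_rows["ipre"] > 0).all()
        assert (feature_rows["udose"] >= 0).all()
        # BID protocol: daily dose is twice a positive per-dose amount
        assert (feature_rows["amt"] > 0).all()

    def test_one_step_ahead_forecast_differs_from_leaky(self):
        records = generate_cohort(short_config(n_patients=3, seed=53))
        honest = build_feature_table(records, structural_preset(), leaky=False)
        leaky = build_feature_table(records, structural_preset(), leaky=True)
        # leaky IPRE conditions on the current trough, honest does not
        assert not np.allclose(honest["ipre"], leaky["ipre"])
        # conditioning on the target must fit it better
        err_honest = np.abs(np.log(honest["ipre"]) - np.log(honest["target"])).mean()
        err_leaky = np.abs(np.log(leaky["ipre"]) - np.log(leaky["target"])).mean()
        assert err_leaky < err_honest


class TestGroupFolds:
    def test_patient_disjointness_and_coverage(self, feature_rows, rng):
        ids = feature_rows["patient_id"].to_numpy()
        folds = _group_folds(ids, 5, rng)
        seen = set()
        for fold in folds:
            fold_ids = set(ids[fold])
            assert fold_ids.isdisjoint(seen)
            seen |= fold_ids
        assert seen == set(ids)

    def test_too_few_patients(self, rng):
        with pytest.raises(ValueError):
            _group_folds(np.array(["a", "b"]), 5, rng)


class TestTuneNestedCv:
    def test_deterministic_for_fixed_seed(self, feature_rows):
        kwargs = dict(n_trials=4, seed=9, inner_folds=3, outer_folds=3)
        a = tune_nested_cv(feature_rows, "xgb", **kwargs)
        b = tune_nested_cv(feature_rows, "xgb", **kwargs)
        assert a.hyperparameters == b.hyperparameters
        assert a.outer_mae == b.outer_mae

    def test_single_trial_still_reports_outer_metrics(self, feature_rows):
        tuned = tune_nested_cv(
            feature_rows, "xgb", n_trials=1, seed=1, inner_folds=3, outer_folds=3
        )
        assert len(tuned.outer_cv_metrics) == 3
        assert np.isfinite(tuned.outer_mae)

    def test_no_patient_leakage_in_outer_predictions(self, feature_rows):
        tuned = tune_nested_cv(
            feature_rows, "xgb", n_trials=2, seed=2, inner_folds=3, outer_folds=4
        )
        preds = tuned.outer_predictions
        # every patient predicted exactly in one fold
        fold_of = preds.groupby("patient_id")["fold"].nunique()
        assert (fold_of == 1).all()
        assert set(preds["patient_id"]) == set(feature_rows["patient_id"])


class TestFitFinalAndPredict:
    def test_memorization_bound(self, feature_rows):
        train = feature_rows.copy()
        test = feature_rows.copy()
        test["patient_id"] = test["patient_id"] + "_copy"
        tuned = default_tuned(
            n_estimators=400, max_depth=10, learning_rate=0.3, subsample=1.0,
            colsample_bytree=1.0, min_child_weight=0.5, reg_lambda=0.01, gamma=0.0,
        )
        _, report = fit_final_and_predict(train, test, tuned)
        assert report.mae < 0.3

    def test_shared_patients_rejected(self, feature_rows):
        with pytest.raises(ValueError, match="share patient"):
            fit_final_and_predict(feature_rows, feature_rows, default_tuned())

    def test_schema_mismatch_lists_columns(self, feature_rows):
        test = feature_rows.copy()
        test["patient_id"] = test["patient_id"] + "x"
        test = test.drop(columns=["ipre"])
        with pytest.raises(ValueError, match="ipre"):
            fit_final_and_predict(feature_rows, test, default_tuned())

    def test_constant_target_r2_guarded(self, feature_rows):
        train = feature_rows.copy()
        test = feature_rows.iloc[:6].copy()
        test["patient_id"] = "held_out_patient"
        test["target"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            _, report = fit_final_and_predict(train, test, default_tuned())
        assert report.r2 == 0.0

    def test_ipre_feature_improves_test_error_majority_of_seeds(self):
        wins = 0
        for seed in range(5):
            records = generate_cohort(short_config(n_patients=24, seed=300 + seed))
            rows = build_feature_table(records, structural_preset())
            ids = sorted(set(rows["patient_id"]))
            train = rows[rows["patient_id"].isin(ids[:18])]
            test = rows[rows["patient_id"].isin(ids[18:])]
            _, with_ipre = fit_final_and_predict(train, test, default_tuned())
            _, without = fit_final_and_predict(
                train.drop(columns=["ipre"]), test.drop(columns=["ipre"]),
                default_tuned(),
            )
            wins += with_ipre.mae < without.mae
        assert wins >= 3


class TestAttribution:
    def test_tree_additivity_and_agreement_with_booster(self, feature_rows):
        est = make_estimator("xgb", default_hyperparameters("xgb"), seed=3)
        X = feature_rows[_feature_columns(feature_rows)].to_numpy(float)
        est.fit(X, feature_rows["target"].to_numpy(float))
        precise = feature_attribution(est, feature_rows.iloc[:80], precise=True)
        assert precise.exact
        assert precise.reconstruction_error() < 1e-9
        fast = feature_attribution(est, feature_rows.iloc[:80], precise=False)
        assert np.abs(precise.values - fast.values).max() < 1e-4

    def test_planted_signal_ranks_ipre_first(self, feature_rows):
        rows = feature_rows.copy()
        rows["target"] = 1.5 * rows["ipre"]
        est = make_estimator("xgb", default_hyperparameters("xgb"), seed=4)
        est.fit(
            rows[_feature_columns(rows)].to_numpy(float),
            rows["target"].to_numpy(float),
        )
        att = feature_attribution(est, rows)
        assert att.ranking["feature"].iloc[0] == "ipre"

    def test_ignored_feature_attributes_nothing(self, feature_rows, rng):
        rows = feature_rows.copy()
        rows["target"] = 1.5 * rows["ipre"]
        rows["bun"] = rng.permutation(rows["bun"].to_numpy())  # pure noise now
        est = make_estimator("xgb", default_hyperparameters("xgb"), seed=5)
        est.fit(
            rows[_feature_columns(rows)].to_numpy(float),
            rows["target"].to_numpy(float),
        )
        att = feature_attribution(est, rows)
        ranking = att.ranking.set_index("feature")["mean_abs_attribution"]
        assert ranking["bun"] < 0.05 * ranking.iloc[0]

    def test_sampling_fallback_for_svr(self, feature_rows):
        est = make_estimator("svr", default_hyperparameters("svr"), seed=6)
        est.fit(
            feature_rows[_feature_columns(feature_rows)].to_numpy(float),
            feature_rows["target"].to_numpy(float),
        )
        att = feature_attribution(est, feature_rows.iloc[:40], seed=6)
        assert not att.exact
        assert att.values.shape == (40, len(_feature_columns(feature_rows)))
        # Monte-Carlo additivity: loose tolerance
        assert att.reconstruction_error() < 1.5


class TestPerOccasionErrors:
    def test_perfect_predictions_zero_mpe(self, feature_rows):
        out = per_occasion_errors(feature_rows["target"].to_numpy(), feature_rows)
        assert all(rep.mpe_pct == pytest.approx(0.0) for rep in out.values())
        assert "7+" in out  # the short schedule has 8 occasions

    def test_single_occasion_group(self, feature_rows):
        rows = feature_rows[feature_rows["occasion_index"] == 2]
        out = per_occasion_errors(rows["target"].to_numpy() * 1.1, rows)
        assert list(out) == ["2"]

    def test_groups_cover_all_predictions(self, feature_rows):
        pred = feature_rows["target"].to_numpy() * 1.05
        out = per_occasion_errors(pred, feature_rows)
        assert sum(rep.n for rep in out.values()) == len(feature_rows)
        assert all(int(k.rstrip("+")) <= 7 for k in out)
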