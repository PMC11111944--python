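"""Event-table data model, round-trip I/O and patient-level splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from tacppk import (
    DosingEvent,
    PatientRecord,
    TroughObservation,
    ValidationError,
    generate_cohort,
    read_event_table,
    split_train_test,
    write_event_table,
)
from tacppk.io import MANDATORY_COLUMNS, SchemaError
from tacppk.simulate import CohortConfig

from conftest import make_panel, make_record, short_config


def records_equal(a: PatientRecord, b: PatientRecord) -> bool:
    if a.patient_id != b.patient_id:
        return False
    if len(a.doses) != len(b.doses) or len(a.observations) != len(b.observations):
        return False
    for da, db in zip(a.doses, b.doses):
        if abs(da.time - db.time) > 1e-9 or abs(da.amount - db.amount) > 1e-9:
            return False
    for oa, ob in zip(a.observations, b.observations):
        if (
            abs(oa.time - ob.time) > 1e-9
            or abs(oa.conc - ob.conc) > 1e-9
            or oa.censored != ob.censored
            or oa.occasion_index != ob.occasion_index
            or abs(oa.pod - ob.pod) > 1e-9
        ):
            return False
    for i in range(len(a.observations)):
        pa, pb = a.panel_for_observation(i), b.panel_for_observation(i)
        for field in (
            "wt", "hct", "rbc", "dbil", "bun", "clcr", "alb",
            "sex_code", "cyp3a5_code", "comed_ca_antagonist",
            "comed_ppi", "comed_voriconazole",
        ):
            if abs(float(getattr(pa, field)) - float(getattr(pb, field))) > 1e-9:
                return False
    return True


class TestDataModel:
    def test_negative_dose_amount_rejected(self):
        with pytest.raises(ValidationError):
            DosingEvent(0.0, -1.0)

    def test_out_of_range_conc_needs_censor_flag(self):
        with pytest.raises(ValidationError):
            TroughObservation(time=24.0, conc=1.5, pod=1.0, occasion_index=1)
        obs = TroughObservation(
            time=24.0, conc=1.5, pod=1.0, occasion_index=1, censored=True
        )
        assert obs.censored

    def test_observation_before_first_dose_rejected(self):
        with pytest.raises(ValidationError, match="P9"):
            PatientRecord(
                "P9",
                [DosingEvent(48.0, 3.0)],
                [TroughObservation(time=24.0, conc=5.0, pod=1.0, occasion_index=1)],
                [make_panel()],
            )

    def test_invalid_genotype_code_rejected(self):
        with pytest.raises(ValidationError):
            make_panel(cyp3a5_code=3)


class TestEventTableIO:
    def test_minimal_two_row_file(self, tmp_path):
        path = tmp_path / "ev.csv"
        rec = make_record(obs_times=(72.0,), concs=(6.0,))
        write_event_table([rec], path)
        frame = pd.read_csv(path)
        assert (frame["MDV"] == 1).sum() == len(rec.doses)
        assert (frame["MDV"] == 0).sum() == 1
        back = read_event_table(path)
        assert len(back) == 1
        assert records_equal(rec, back[0])

    def test_round_trip_synthetic_patients(self, tmp_path):
        records = generate_cohort(short_config(n_patients=3, seed=5))
        path = tmp_path / "ev.csv"
        write_event_table(records, path)
        back = read_event_table(path)
        assert len(back) == 3
        for a, b in zip(records, back):
            assert records_equal(a, b)

    def test_row_count_preserved(self, tmp_path):
        records = generate_cohort(short_config(n_patients=3, seed=5))
        path = tmp_path / "ev.csv"
        write_event_table(records, path)
        frame = pd.read_csv(path)
        expected = sum(len(r.doses) + len(r.observations) for r in records)
        assert len(frame) == expected

    def test_low_dv_flagged_censored_on_read(self, tmp_path):
        path = tmp_path / "ev.csv"
        rec = make_record(obs_times=(72.0, 168.0), concs=(1.5, 6.0))
        write_event_table([rec], path)
        back = read_event_table(path)[0]
        assert back.observations[0].censored
        assert not back.observations[1].censored
        assert back.observations[0].conc == pytest.approx(1.5)

    def test_time_varying_hct_preserved(self, tmp_path):
        panels = [make_panel(hct=0.25), make_panel(hct=0.35)]
        rec = make_record()
        rec = PatientRecord(rec.patient_id, rec.doses, rec.observations, panels)
        path = tmp_path / "ev.csv"
        write_event_table([rec], path)
        back = read_event_table(path)[0]
        assert back.panel_for_observation(0).hct == pytest.approx(0.25)
        assert back.panel_for_observation(1).hct == pytest.approx(0.35)

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_event_table([], path)
        frame = pd.read_csv(path)
        assert len(frame) == 0
        assert list(frame.columns) == MANDATORY_COLUMNS

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"ID": ["a"], "TIME": [0.0]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="AMT"):
            read_event_table(path)

    def test_observation_before_dose_names_patient(self, tmp_path):
        path = tmp_path / "bad.csv"
        rec = make_record(patient_id="PX")
        write_event_table([rec], path)
        frame = pd.read_csv(path)
        # move the first observation before every dose
        obs_rows = frame["MDV"] == 0
        frame.loc[obs_rows.idxmax(), "TIME"] = -1.0
        frame.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="PX"):
            read_event_table(path)

    @settings(
        max_examples=20,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        n_obs=st.integers(1, 5),
        amount=st.floats(0.5, 10.0),
        concs=st.lists(st.floats(2.5, 45.0), min_size=5, max_size=5),
        hcts=st.lists(st.floats(0.2, 0.45), min_size=5, max_size=5),
    )
    def test_round_trip_property(self, tmp_path, n_obs, amount, concs, hcts):
        obs_times = tuple(72.0 + 24.0 * i for i in range(n_obs))
        rec = make_record(
            amount=round(amount, 3),
            obs_times=obs_times,
            concs=tuple(round(c, 4) for c in concs[:n_obs]),
        )
        panels = [make_panel(hct=round(h, 4)) for h in hcts[:n_obs]]
        rec = PatientRecord(rec.patient_id, rec.doses, rec.observations, panels)
        path = tmp_path / "prop.csv"
        write_event_table([rec], path)
        assert records_equal(rec, read_event_table(path)[0])


class TestSplit:
    def test_deterministic_and_disjoint(self, small_cohort):
        t1, s1 = split_train_test(small_cohort, 0.8, seed=42)
        t2, s2 = split_train_test(small_cohort, 0.8, seed=42)
        ids = lambda rs: {r.patient_id for r in rs}
        assert ids(t1) == ids(t2) and ids(s1) == ids(s2)
        assert ids(t1).isdisjoint(ids(s1))
        assert ids(t1) | ids(s1) == ids(small_cohort)

    def test_ten_patients_eight_two(self):
        records = generate_cohort(short_config(n_patients=10, seed=2))
        train, test = split_train_test(records, 0.8, seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_proportion_near_fraction_at_cohort_scale(self):
        records = generate_cohort(
            CohortConfig(n_patients=127, seed=3, sampling_schedule=(3, 7))
        )
        train, test = split_train_test(records, 0.8, seed=0)
        assert abs(len(train) - 0.8 * 127) <= 1.0
        assert len(train) + len(test) == 127

    def test_bad_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            split_train_test(small_cohort, 1.2, seed=0)

    def test_too_few_patients_rejected(self):
        records = generate_cohort(short_config(n_patients=4, seed=2))
        with pytest.raises(ValueError):
            split_train_test(records, 0.8, seed=0)
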