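import numpy as np
import pytest

from tacppk import CohortConfig, CovariatePanel, DosingEvent, PatientRecord, TroughObservation
from tacppk.simulate import generate_cohort


def make_panel(**overrides) -> CovariatePanel:
    values = dict(
        wt=60.0,
        hct=0.29,
        rbc=3.0,
        dbil=2.5,
        bun=18.0,
        clcr=55.0,
        alb=34.0,
        sex_code=0,
        cyp3a5_code=2,
        comed_ca_antagonist=1,
        comed_ppi=1,
        comed_voriconazole=0,
    )
    values.update(overrides)
    return CovariatePanel(**values)


def make_record(
    patient_id="P1",
    dose_times=(0.0, 12.0, 24.0, 36.0, 48.0, 60.0),
    amount=3.0,
    obs_times=(72.0, 168.0),
    concs=(6.0, 8.0),
    panel=None,
) -> PatientRecord:
    """A small well-formed record (doses cover every observation)."""
    doses = [DosingEvent(t, amount) for t in dose_times]
    # extend BID dosing to cover the observation span
    t = dose_times[-1] + 12.0
    while t < max(obs_times):
        doses.append(DosingEvent(t, amount))
        t += 12.0
    obs = [
        TroughObservation(
            time=t,
            conc=c,
            pod=t / 24.0,
            occasion_index=i + 1,
            censored=not (2.0 <= c <= 50.0),
        )
        for i, (t, c) in enumerate(zip(obs_times, concs))
    ]
    panels = [panel or make_panel() for _ in obs]
    return PatientRecord(patient_id, doses, obs, panels)


#: short TDM schedule used to keep estimation tests fast
SHORT_SCHEDULE = (3, 7, 14, 28, 56, 90, 150, 210)


def short_config(n_patients=20, seed=0, **overrides) -> CohortConfig:
    kwargs = dict(
        n_patients=n_patients, seed=seed, sampling_schedule=SHORT_SCHEDULE
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients, 8 troughs each, final-model generative parameters."""
    return generate_cohort(short_config(n_patients=20, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
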