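"""Synthetic renal-transplant TDM cohorts with known ground truth.

The generator emulates the statistical structure of a conventional
tacrolimus monitoring dataset in adult renal-transplant recipients:

* CYP3A5 *3 allele-count genotypes drawn at the cohort frequencies
  (defaults 9.45% / 33.9% / 56.7% for codes 0/1/2);
* covariates drawn from truncated normal / lognormal marginals matching
  the cohort summary statistics (e.g. HCT 0.29 +/- 0.056 as a fraction),
  with small within-patient day-to-day lab variation;
* protocol dosing at 0.1 mg/kg/day split twice daily, titrated after
  each trough toward 10-13 ng/mL in the first month and 5-9 ng/mL
  thereafter (multiplier 0.75 / 1.25, re-rounded to 0.5 mg);
* troughs simulated from the one-compartment model with lognormal
  between-subject variability and a log-additive residual, censored
  outside the 2-50 ng/mL assay range (flagged, not dropped).

Latent etas and individual parameters are recorded per patient so that
estimation and selection runs can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ASSAY_LOWER,
    ASSAY_UPPER,
    CovariatePanel,
    DosingEvent,
    PatientRecord,
    TroughObservation,
)
from .pk_model import PopulationModel, final_preset, individualize, predict_concentration

__all__ = ["CohortConfig", "generate_cohort", "truth_table"]

_TRUTH_ATTR = "_tacppk_truth"

#: default trough schedule, postoperative days (~16 TDM visits spanning
#: the first post-transplant year)
DEFAULT_SCHEDULE = (3, 5, 7, 10, 14, 21, 28, 35, 42, 56, 70, 90, 120, 180, 270, 365)


@dataclass(frozen=True)
class _TruncNormal:
    mean: float
    sd: float
    lower: float
    upper: float

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lower <= x <= self.upper:
                return float(x)
        return float(np.clip(self.mean, self.lower, self.upper))


@dataclass(frozen=True)
class _LogNormal:
    """Parameterized by the natural-scale mean and SD (moment-matched)."""

    mean: float
    sd: float
    lower: float = 0.0
    upper: float = np.inf

    def draw(self, rng: np.random.Generator) -> float:
        cv2 = (self.sd / self.mean) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(self.mean) - 0.5 * sigma**2
        for _ in range(1000):
            x = rng.lognormal(mu, sigma)
            if self.lower <= x <= self.upper:
                return float(x)
        return float(np.clip(self.mean, self.lower, self.upper))


@dataclass
class CohortConfig:
    """Everything needed to generate a cohort reproducibly."""

    n_patients: int = 127
    genotype_freqs: tuple[float, float, float] = (0.0945, 0.339, 0.567)
    p_female: float = 0.38
    comed_freqs: dict = field(
        default_factory=lambda: {
            "comed_ca_antagonist": 0.786,
            "comed_ppi": 0.99,
            "comed_voriconazole": 0.204,
        }
    )
    covariate_distributions: dict = field(
        default_factory=lambda: {
            "wt": _TruncNormal(63.3, 12.9, 40.0, 110.0),
            "hct": _TruncNormal(0.29, 0.056, 0.16, 0.50),
            "rbc": _TruncNormal(3.06, 0.61, 1.2, 6.0),
            "dbil": _LogNormal(2.58, 1.17, 0.3, 15.0),
            "bun": _TruncNormal(18.8, 10.5, 3.0, 60.0),
            "clcr": _LogNormal(55.0, 30.0, 8.0, 160.0),
            "alb": _TruncNormal(34.0, 3.69, 20.0, 50.0),
        }
    )
    #: day-to-day within-patient lab variation (absolute SD for hct,
    #: relative SD for the other labs)
    hct_within_sd: float = 0.015
    lab_within_rel_sd: float = 0.05
    #: protocol: 0.1 mg/kg/day split BID, per-dose rounding grain in mg
    initial_mg_per_kg_per_day: float = 0.1
    dose_rounding_mg: float = 0.5
    dose_interval_h: float = 12.0
    titration_up: float = 1.25
    titration_down: float = 0.75
    #: target windows (ng/mL): first month, then maintenance
    early_window: tuple[float, float] = (10.0, 13.0)
    late_window: tuple[float, float] = (5.0, 9.0)
    early_window_days: float = 30.0
    sampling_schedule: tuple = DEFAULT_SCHEDULE
    generative_params: PopulationModel = field(default_factory=final_preset)
    #: optional extra exponential effect of voriconazole co-medication on
    #: CL/F (0 = off); used to probe covariate-selection power
    voriconazole_cl_beta: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.genotype_freqs) - 1.0) > 0.01:
            raise ValueError(f"genotype_freqs must sum to 1, got {self.genotype_freqs}")
        if any(f < 0 for f in self.genotype_freqs):
            raise ValueError("genotype frequencies must be non-negative")
        for name, dist in self.covariate_distributions.items():
            if dist.sd < 0:
                raise ValueError(f"{name}: negative SD")
        if not self.sampling_schedule or any(
            b <= a for a, b in zip(self.sampling_schedule, self.sampling_schedule[1:])
        ):
            raise ValueError("sampling_schedule must be strictly increasing")


def _round_dose(amount: float, grain: float) -> float:
    return max(grain, round(amount / grain) * grain)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[PatientRecord]:
    """Generate a cohort; latent truths are attached for :func:`truth_table`."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    model = config.generative_params
    records: list[PatientRecord] = []
    width = max(3, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        freqs = np.asarray(config.genotype_freqs, dtype=float)
        genotype = int(rng.choice(3, p=freqs / freqs.sum()))
        sex = int(rng.random() < config.p_female)
        comeds = {
            name: int(rng.random() < freq) for name, freq in config.comed_freqs.items()
        }
        base = {
            name: dist.draw(rng) for name, dist in config.covariate_distributions.items()
        }
        eta_v = rng.normal(0.0, np.sqrt(model.omega2_v))
        eta_cl = rng.normal(0.0, np.sqrt(model.omega2_cl))
        cov_values = dict(base, cyp3a5_code=genotype, sex_code=sex, **comeds)
        ind = individualize(model, cov_values, eta_v=eta_v, eta_cl=eta_cl)
        if config.voriconazole_cl_beta and comeds.get("comed_voriconazole"):
            ind = replace(ind, cl_f=ind.cl_f * np.exp(config.voriconazole_cl_beta))

        per_dose = _round_dose(
            0.5 * config.initial_mg_per_kg_per_day * base["wt"], config.dose_rounding_mg
        )
        doses: list[DosingEvent] = []
        observations: list[TroughObservation] = []
        panels: list[CovariatePanel] = []
        t_dose = 0.0
        for occ, pod in enumerate(config.sampling_schedule, start=1):
            t_obs = 24.0 * pod
            while t_dose < t_obs:
                doses.append(DosingEvent(time=t_dose, amount=per_dose))
                t_dose += config.dose_interval_h
            true_conc = predict_concentration(ind, model.ka, doses, t_obs)
            eps = rng.normal(0.0, np.sqrt(model.sigma2))
            conc = float(true_conc * np.exp(eps))
            censored = not (ASSAY_LOWER <= conc <= ASSAY_UPPER)
            observations.append(
                TroughObservation(
                    time=t_obs, conc=conc, pod=float(pod), occasion_index=occ,
                    censored=censored,
                )
            )
            panels.append(_jitter_panel(config, rng, base, genotype, sex, comeds))
            window = (
                config.early_window
                if pod <= config.early_window_days
                else config.late_window
            )
            if conc > window[1]:
                per_dose = _round_dose(
                    per_dose * config.titration_down, config.dose_rounding_mg
                )
            elif conc < window[0]:
                per_dose = _round_dose(
                    per_dose * config.titration_up, config.dose_rounding_mg
                )
        record = PatientRecord(pid, doses, observations, panels)
        setattr(
            record,
            _TRUTH_ATTR,
            {
                "patient_id": pid,
                "eta_v": float(eta_v),
                "eta_cl": float(eta_cl),
                "v_f": float(ind.v_f),
                "cl_f": float(ind.cl_f),
                "cyp3a5_code": genotype,
                "hct": float(base["hct"]),
            },
        )
        records.append(record)
    return records


def _jitter_panel(config, rng, base, genotype, sex, comeds) -> CovariatePanel:
    dists = config.covariate_distributions
    values = {}
    for name, b in base.items():
        if name == "hct":
            lo, hi = dists[name].lower, dists[name].upper
            values[name] = float(np.clip(rng.normal(b, config.hct_within_sd), lo, hi))
        else:
            lo = getattr(dists[name], "lower", 0.0) or 1e-6
            jit = b * (1.0 + rng.normal(0.0, config.lab_within_rel_sd))
            values[name] = float(max(jit, lo))
    return CovariatePanel(
        sex_code=sex, cyp3a5_code=genotype, **values, **comeds
    )


def truth_table(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Latent (eta_v, eta_cl, true CL/F, V/F) per generated patient."""
    rows = []
    for rec in cohort:
        truth = getattr(rec, _TRUTH_ATTR, None)
        if truth is None:
            raise ValueError(
                f"patient {rec.patient_id} was not produced by generate_cohort; "
                "no latent truth is available"
            )
        rows.append(truth)
    return pd.DataFrame(rows).set_index("patient_id")
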