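"""Longitudinal therapeutic-drug-monitoring data model.

Tacrolimus trough (C0) monitoring data are naturally event-structured:
each patient contributes an ordered sequence of oral dosing events and
pre-dose trough observations, together with the covariate panel recorded
on each monitoring day.  These types are the canonical in-memory
representation shared by the PK engine, the estimation machinery and the
machine-learning feature builder.

Units are fixed by convention and never auto-converted: time in hours
since the first post-transplant dose, dose amounts in mg, concentrations
in ng/mL, hematocrit as a fraction (0.29-style), weight in kg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ASSAY_LOWER",
    "ASSAY_UPPER",
    "COVARIATE_FIELDS",
    "DosingEvent",
    "TroughObservation",
    "CovariatePanel",
    "PatientRecord",
    "ValidationError",
]

#: Immunoassay quantification range, ng/mL.  Troughs outside this window
#: are retained but flagged censored and excluded from estimation and
#: from machine-learning targets.
ASSAY_LOWER = 2.0
ASSAY_UPPER = 50.0


class ValidationError(ValueError):
    """A record violates a structural invariant (named in the message)."""


@dataclass(frozen=True)
class DosingEvent:
    """One oral tacrolimus dose.

    Attributes
    ----------
    time : float
        Hours since the first post-transplant dose (>= 0).
    amount : float
        Dose in mg (> 0).  This is the per-administration amount; the
        protocol is twice-daily, so the daily dose is twice this value
        while a schedule is constant.
    """

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValidationError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class TroughObservation:
    """One pre-dose (C0) concentration measurement.

    ``censored`` marks values outside the assay range [2, 50] ng/mL; the
    raw value is kept so round-tripping through files is lossless.
    ``occasion_index`` is the 1-based ordinal of the TDM visit.
    """

    time: float
    conc: float
    pod: float
    occasion_index: int
    censored: bool = False

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValidationError(f"concentration must be > 0, got {self.conc}")
        in_range = ASSAY_LOWER <= self.conc <= ASSAY_UPPER
        if not in_range and not self.censored:
            raise ValidationError(
                f"concentration {self.conc} ng/mL outside assay range "
                f"[{ASSAY_LOWER}, {ASSAY_UPPER}] must carry censored=True"
            )


#: Covariate panel field -> event-table column, in canonical column order.
COVARIATE_FIELDS = {
    "wt": "WT",
    "hct": "HCT",
    "rbc": "RBC",
    "dbil": "DBIL",
    "bun": "BUN",
    "clcr": "CLCR",
    "alb": "ALB",
    "sex_code": "SEX",
    "cyp3a5_code": "CYP3A5",
    "comed_ca_antagonist": "COMED_CA",
    "comed_ppi": "COMED_PPI",
    "comed_voriconazole": "COMED_VORI",
}


@dataclass(frozen=True)
class CovariatePanel:
    """Covariates recorded on one monitoring day.

    ``cyp3a5_code`` counts *3 alleles: 0 = *1/*1 (expresser),
    1 = *1/*3, 2 = *3/*3 (non-expresser).  ``hct`` is a fraction.
    """

    wt: float
    hct: float
    rbc: float
    dbil: float
    bun: float
    clcr: float
    alb: float
    sex_code: int
    cyp3a5_code: int
    comed_ca_antagonist: int = 0
    comed_ppi: int = 0
    comed_voriconazole: int = 0

    def __post_init__(self) -> None:
        if self.cyp3a5_code not in (0, 1, 2):
            raise ValidationError(
                f"cyp3a5_code must be 0, 1 or 2, got {self.cyp3a5_code}"
            )
        if self.sex_code not in (0, 1):
            raise ValidationError(f"sex_code must be 0 or 1, got {self.sex_code}")
        # NaN marks a missing lab value; such rows are dropped by the
        # ML feature builder and excluded from covariate summaries
        import math

        if not (math.isnan(self.hct) or 0 < self.hct < 1):
            raise ValidationError(f"hct must be a fraction in (0, 1), got {self.hct}")
        for name in ("wt", "rbc", "dbil", "bun", "clcr", "alb"):
            value = getattr(self, name)
            if value <= 0:  # NaN passes: missing, not invalid
                raise ValidationError(f"{name} must be > 0, got {value}")


@dataclass
class PatientRecord:
    """Dosing history, trough observations and covariates for one subject.

    ``covariates`` carries one panel per observation (time-varying labs);
    a record with a single panel is interpreted as time-constant.
    """

    patient_id: str
    doses: list[DosingEvent]
    observations: list[TroughObservation]
    covariates: list[CovariatePanel]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.doses:
            raise ValidationError(f"patient {self.patient_id}: no dosing events")
        dose_times = [d.time for d in self.doses]
        if sorted(dose_times) != dose_times:
            raise ValidationError(
                f"patient {self.patient_id}: dosing events not time-sorted"
            )
        obs_times = [o.time for o in self.observations]
        if sorted(obs_times) != obs_times:
            raise ValidationError(
                f"patient {self.patient_id}: observations not time-sorted"
            )
        first_dose = dose_times[0]
        for obs in self.observations:
            if obs.time <= first_dose:
                raise ValidationError(
                    f"patient {self.patient_id}: observation at t={obs.time} h "
                    f"precedes the first dose at t={first_dose} h"
                )
        occ = [o.occasion_index for o in self.observations]
        if occ != list(range(1, len(occ) + 1)):
            raise ValidationError(
                f"patient {self.patient_id}: occasion indices must be 1..n "
                f"consecutive, got {occ}"
            )
        if not self.covariates:
            raise ValidationError(f"patient {self.patient_id}: no covariate panel")
        if self.observations and len(self.covariates) not in (1, len(self.observations)):
            raise ValidationError(
                f"patient {self.patient_id}: need 1 covariate panel or one per "
                f"observation ({len(self.observations)}), got {len(self.covariates)}"
            )

    # -- convenience accessors -------------------------------------------------

    def panel_for_observation(self, index: int) -> CovariatePanel:
        """Covariate panel aligned with the ``index``-th observation."""
        if len(self.covariates) == 1:
            return self.covariates[0]
        return self.covariates[index]

    @property
    def usable_observations(self) -> list[TroughObservation]:
        """Observations inside the assay range (used for estimation/ML)."""
        return [o for o in self.observations if not o.censored]

    def with_observations(
        self, observations: Sequence[TroughObservation], covariates: Sequence[CovariatePanel] | None = None
    ) -> "PatientRecord":
        """Copy of the record with a replaced observation list."""
        obs = list(observations)
        cov = list(covariates) if covariates is not None else list(self.covariates)
        return PatientRecord(self.patient_id, list(self.doses), obs, cov)


def check_unique_ids(records: Iterable[PatientRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise ValidationError(f"duplicate patient id {rec.patient_id!r}")
        seen.add(rec.patient_id)
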