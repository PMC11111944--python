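"""Event-table reading/writing and patient-level train/test splitting.

The on-disk format is a NONMEM-style event CSV: one row per dose
(``AMT`` > 0, ``MDV`` = 1) or trough observation (``DV`` set,
``MDV`` = 0), grouped by ``ID`` and sorted by ``TIME`` within a patient.
Covariate columns are snapshots taken on monitoring days; dose rows
carry the last observed panel forward.  Troughs outside the assay
quantification range are loaded and flagged censored, never dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ASSAY_LOWER,
    ASSAY_UPPER,
    COVARIATE_FIELDS,
    CovariatePanel,
    DosingEvent,
    PatientRecord,
    TroughObservation,
    check_unique_ids,
)

__all__ = ["SchemaError", "read_event_table", "write_event_table", "split_train_test"]

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "DV", "MDV", "POD"] + list(
    COVARIATE_FIELDS.values()
)

_INT_FIELDS = {
    "sex_code",
    "cyp3a5_code",
    "comed_ca_antagonist",
    "comed_ppi",
    "comed_voriconazole",
}


class SchemaError(ValueError):
    """The event table is missing or mistyping a mandatory column."""


def _panel_from_row(row: pd.Series) -> CovariatePanel:
    kwargs = {}
    for field, column in COVARIATE_FIELDS.items():
        value = row[column]
        kwargs[field] = int(value) if field in _INT_FIELDS else float(value)
    return CovariatePanel(**kwargs)


def read_event_table(path: str | Path) -> list[PatientRecord]:
    """Load a NONMEM-style event CSV into :class:`PatientRecord` objects.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    ValidationError
        If a patient's rows violate a structural invariant, e.g. an
        observation earlier than the first dose (the message names the
        patient).
    """
    frame = pd.read_csv(path, dtype={"ID": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"event table is missing mandatory column(s): {missing}")
    records: list[PatientRecord] = []
    for pid, group in frame.groupby("ID", sort=False):
        group = group.sort_values("TIME", kind="stable")
        doses: list[DosingEvent] = []
        observations: list[TroughObservation] = []
        panels: list[CovariatePanel] = []
        occ = 0
        for _, row in group.iterrows():
            mdv = int(row["MDV"]) if not _isna(row["MDV"]) else 1
            amt = float(row["AMT"]) if not _isna(row["AMT"]) else 0.0
            if mdv == 1 or (amt > 0 and _isna(row["DV"])):
                doses.append(DosingEvent(time=float(row["TIME"]), amount=amt))
            else:
                dv = float(row["DV"])
                occ += 1
                censored = not (ASSAY_LOWER <= dv <= ASSAY_UPPER)
                observations.append(
                    TroughObservation(
                        time=float(row["TIME"]),
                        conc=dv,
                        pod=float(row["POD"]),
                        occasion_index=occ,
                        censored=censored,
                    )
                )
                panels.append(_panel_from_row(row))
        if not panels:
            # dose-only record: take the panel carried on the last dose row
            panels = [_panel_from_row(group.iloc[-1])]
        records.append(PatientRecord(str(pid), doses, observations, panels))
    check_unique_ids(records)
    return records


def write_event_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as an event CSV; inverse of :func:`read_event_table`."""
    rows: list[dict] = []
    for rec in records:
        events: list[tuple[float, int, object]] = [(d.time, 1, d) for d in rec.doses]
        events += [(o.time, 0, (i, o)) for i, o in enumerate(rec.observations)]
        # doses sort before a simultaneous observation (pre-dose troughs
        # are recorded at the instant before the next dose)
        events.sort(key=lambda e: (e[0], -e[1]))
        last_panel = rec.covariates[0]
        for time, is_dose, payload in events:
            if is_dose:
                dose = payload
                row = {
                    "ID": rec.patient_id,
                    "TIME": dose.time,
                    "AMT": dose.amount,
                    "DV": np.nan,
                    "MDV": 1,
                    "POD": math.floor(dose.time / 24.0),
                }
                panel = last_panel
            else:
                idx, obs = payload
                panel = rec.panel_for_observation(idx)
                last_panel = panel
                row = {
                    "ID": rec.patient_id,
                    "TIME": obs.time,
                    "AMT": np.nan,
                    "DV": obs.conc,
                    "MDV": 0,
                    "POD": obs.pod,
                }
            for field, column in COVARIATE_FIELDS.items():
                row[column] = getattr(panel, field)
            rows.append(row)
    frame = pd.DataFrame(rows, columns=MANDATORY_COLUMNS[:6] + list(COVARIATE_FIELDS.values()))
    if not rows:
        frame = pd.DataFrame(columns=MANDATORY_COLUMNS)
    frame.to_csv(path, index=False)


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value)


def split_train_test(
    records: Sequence[PatientRecord], fraction: float = 0.8, seed: int = 0
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Randomly partition patients into training and test sets.

    The split is by patient: no subject contributes rows to both sets.
    Deterministic for a fixed ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if len(records) < 5:
        raise ValueError(f"need at least 5 patients to split, got {len(records)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(fraction * len(records)))
    n_train = min(max(n_train, 1), len(records) - 1)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return [records[i] for i in train_idx], [records[i] for i in test_idx]
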