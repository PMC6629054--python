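"""Patient-level inclusion/exclusion rules and attrition reporting.

A hospitalization is included iff the discharge time is present, at least two
inpatient creatinine values were measured, no end-stage kidney disease (ESKD)
code is flagged, and the admission creatinine — the chronologically first
inpatient creatinine of the admission — is below 4.0 mg/dL.  Exclusions are
attributed sequentially (first rule wins), mirroring a cohort flow diagram.

ESKD status is consumed as a boolean input column rather than derived from
ICD codes: code lists are institution-specific and belong in upstream ETL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import SchemaError

#: mg/dL; admissions starting at or above this creatinine are excluded.
ADMISSION_CREATININE_CUTOFF = 4.0

#: Rule order for first-rule-wins attribution.
RULE_ORDER = (
    "missing_discharge",
    "fewer_than_two_creatinines",
    "eskd_code",
    "admission_creatinine_ge_4",
)


@dataclass
class ExclusionReport:
    """Attrition counts, one bucket per exclusion rule plus the included count."""

    n_input: int = 0
    missing_discharge: int = 0
    fewer_than_two_creatinines: int = 0
    eskd_code: int = 0
    admission_creatinine_ge_4: int = 0
    included: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.included


def apply_exclusions(
    patients: pd.DataFrame, measurements: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter a patient table by the study exclusion rules.

    Parameters
    ----------
    patients
        One row per hospitalization with at least ``patient_id``,
        ``discharge_time_h`` (NaN when missing) and ``eskd`` (bool).
    measurements
        Long event table with ``patient_id, time_h, analyte, value``.

    Returns
    -------
    (filtered patients, ExclusionReport)
    """
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicate patient ids: {dupes[:5]}")
    creat = measurements[measurements["analyte"] == "creatinine"]
    if (creat["value"] <= 0).any() or not np.isfinite(creat["value"]).all():
        raise SchemaError("non-positive or non-finite creatinine values in measurements")

    creat_sorted = creat.sort_values(["patient_id", "time_h"], kind="stable")
    n_creat = creat_sorted.groupby("patient_id").size()
    first_creat = creat_sorted.groupby("patient_id")["value"].first()

    report = ExclusionReport(n_input=len(patients))
    excluded_by: dict = {}
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        if pd.isna(row["discharge_time_h"]):
            excluded_by[pid] = "missing_discharge"
        elif n_creat.get(pid, 0) < 2:
            excluded_by[pid] = "fewer_than_two_creatinines"
        elif bool(row["eskd"]):
            excluded_by[pid] = "eskd_code"
        elif first_creat.get(pid, 0.0) >= ADMISSION_CREATININE_CUTOFF:
            excluded_by[pid] = "admission_creatinine_ge_4"
    for rule in RULE_ORDER:
        setattr(report, rule, sum(1 for r in excluded_by.values() if r == rule))
    keep = ~patients["patient_id"].isin(excluded_by)
    filtered = patients.loc[keep].reset_index(drop=True)
    report.included = len(filtered)
    return filtered, report
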