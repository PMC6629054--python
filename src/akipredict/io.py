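"""CSV interchange schemas.

On disk, event times are ISO-8601 calendar timestamps (UTF-8 CSVs with a
header); internally everything runs on real-valued hours from admission.
These helpers convert between the two at the I/O boundary.  Schema versioning
rides in a sidecar written by the pipeline manifest.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = "1"
_BASE_TIME = pd.Timestamp("2013-01-01 00:00:00")

PATIENT_COLUMNS = [
    "patient_id",
    "hospital",
    "admit_time",
    "discharge_time",
    "eskd",
    "age",
    "sex_male",
    "race_black",
    "surgical_admission",
    "chf",
    "hypertension",
    "diabetes",
    "liver_disease",
    "elixhauser",
    "rrt_time",
    "death_time",
]
MEASUREMENT_COLUMNS = ["patient_id", "timestamp", "analyte", "value"]
EXPOSURE_COLUMNS = ["patient_id", "timestamp", "exposure"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _admit_times(patients: pd.DataFrame) -> pd.Series:
    """Deterministic synthetic admission timestamps, staggered by patient."""
    return pd.Series(
        _BASE_TIME + pd.to_timedelta(np.arange(len(patients)) * 7, unit="h"),
        index=patients["patient_id"],
    )


def _to_timestamp(admit: pd.Series, pid: pd.Series, hours: pd.Series) -> pd.Series:
    return admit.loc[pid].to_numpy() + pd.to_timedelta(hours.to_numpy(), unit="h")


def write_cohort(out_dir, patients, measurements, exposures, ground_truth=None) -> dict:
    """Write patients/measurements/exposures (and ground truth) as CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    admit = _admit_times(patients)

    pat = patients.copy()
    pat["admit_time"] = admit.loc[pat["patient_id"]].to_numpy()
    pat["discharge_time"] = pat["admit_time"] + pd.to_timedelta(
        pat["discharge_time_h"], unit="h"
    )
    pat["rrt_time"] = pat["admit_time"] + pd.to_timedelta(pat["rrt_time_h"], unit="h")
    pat["death_time"] = pat["admit_time"] + pd.to_timedelta(pat["death_time_h"], unit="h")
    pat[PATIENT_COLUMNS].to_csv(out / "patients.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")

    meas = measurements.copy()
    meas["timestamp"] = _to_timestamp(admit, meas["patient_id"], meas["time_h"])
    meas[MEASUREMENT_COLUMNS].to_csv(
        out / "measurements.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )

    exp = exposures.copy()
    exp["timestamp"] = _to_timestamp(admit, exp["patient_id"], exp["time_h"])
    exp[EXPOSURE_COLUMNS].to_csv(
        out / "exposures.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )

    paths = {
        "patients": out / "patients.csv",
        "measurements": out / "measurements.csv",
        "exposures": out / "exposures.csv",
    }
    if ground_truth is not None:
        ground_truth.onsets.to_csv(out / "ground_truth.csv", index=False)
        paths["ground_truth"] = out / "ground_truth.csv"
    return {k: str(v) for k, v in paths.items()}


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the CSV cohort back into the internal hours-from-admission form."""
    src = Path(in_dir)
    for name in ("patients.csv", "measurements.csv", "exposures.csv"):
        if not (src / name).exists():
            raise SchemaError(f"missing input file: {src / name}")
    patients = pd.read_csv(
        src / "patients.csv",
        parse_dates=["admit_time", "discharge_time", "rrt_time", "death_time"],
    )
    _require(patients, PATIENT_COLUMNS, src / "patients.csv")
    measurements = pd.read_csv(src / "measurements.csv", parse_dates=["timestamp"])
    _require(measurements, MEASUREMENT_COLUMNS, src / "measurements.csv")
    exposures = pd.read_csv(src / "exposures.csv", parse_dates=["timestamp"])
    _require(exposures, EXPOSURE_COLUMNS, src / "exposures.csv")

    admit = patients.set_index("patient_id")["admit_time"]
    for col in ("discharge_time", "rrt_time", "death_time"):
        patients[col.replace("_time", "_time_h")] = (
            patients[col] - patients["admit_time"]
        ).dt.total_seconds() / 3600.0
    for df in (measurements, exposures):
        df["time_h"] = (
            df["timestamp"].to_numpy() - admit.loc[df["patient_id"]].to_numpy()
        ) / np.timedelta64(1, "h")
    measurements.sort_values(["patient_id", "time_h", "analyte"], kind="stable", inplace=True)
    exposures.sort_values(["patient_id", "time_h"], kind="stable", inplace=True)
    return (
        patients.reset_index(drop=True),
        measurements.reset_index(drop=True),
        exposures.reset_index(drop=True),
    )
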