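"""Discrete-time observation matrix construction.

Each patient contributes one row per distinct event timestamp (a laboratory
measurement or an exposure onset).  Time-varying covariates are carried
forward — a value holds until remeasured — and three creatinine features are
derived at every row: the last measured creatinine, the 7-day rolling
baseline (lowest value strictly before the row time), and the change in
creatinine over the last 48 hours (current value minus the window minimum,
zero when the window holds no prior value).

Rows at or after AKI onset are never emitted; the onset measurement itself —
which by definition already shows the creatinine rise — is censored so it
cannot leak into prediction.  Outcome labels use a half-open 24-hour
lookahead: a row at time ``t`` is positive for an event at time ``T`` iff
``t < T <= t + 24``.  Missing values are encoded as NaN and are never
imputed; the complete-case filter drops rows lacking any covariate required
by the requested model class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import EXPOSURES, LAB_ANALYTES, class_covariates
from .errors import AkiPredictError, ConfigurationError
from .kdigo import ABSOLUTE_WINDOW_H, BASELINE_WINDOW_H, EPS

DEFAULT_HORIZON_H = 24.0

#: Carried-forward analytes (every analyte except raw creatinine, which
#: enters only through its derived features).
_CARRIED_LABS = tuple(a for a in LAB_ANALYTES if a != "creatinine")

_DEMO_COLS = (
    "age",
    "sex_male",
    "race_black",
    "surgical_admission",
    "chf",
    "hypertension",
    "diabetes",
    "liver_disease",
    "elixhauser",
)


def label_rows(
    row_times: np.ndarray, event_time: float | None, horizon: float = DEFAULT_HORIZON_H
) -> np.ndarray:
    """0/1 lookahead labels: 1 iff ``event_time`` lies in ``(t, t + horizon]``."""
    if horizon <= 0:
        raise ConfigurationError(f"horizon must be positive, got {horizon}")
    t = np.asarray(row_times, dtype=float)
    if event_time is None or not np.isfinite(event_time):
        return np.zeros(t.size, dtype=int)
    return ((t < event_time) & (event_time <= t + horizon)).astype(int)


def _locf(obs_t: np.ndarray, obs_v: np.ndarray, query_t: np.ndarray) -> np.ndarray:
    """Latest value at or before each query time; NaN before the first."""
    idx = np.searchsorted(obs_t, query_t, side="right") - 1
    out = np.full(query_t.size, np.nan)
    ok = idx >= 0
    out[ok] = obs_v[idx[ok]]
    return out


def _window_min_exclusive(
    obs_t: np.ndarray, obs_v: np.ndarray, query_t: np.ndarray, window: float
) -> np.ndarray:
    """Min of values with times in ``[t - window, t)`` per query; NaN if empty."""
    out = np.full(query_t.size, np.nan)
    for k, t in enumerate(query_t):
        lo = np.searchsorted(obs_t, t - window - EPS, side="left")
        hi = np.searchsorted(obs_t, t, side="left")
        if hi > lo:
            out[k] = obs_v[lo:hi].min()
    return out


def build_rows(
    patient: pd.Series | dict,
    measurements: pd.DataFrame,
    exposures: pd.DataFrame,
    onset_time: float | None = None,
    sustained: bool = False,
    horizon: float = DEFAULT_HORIZON_H,
) -> pd.DataFrame:
    """Build the observation rows for a single admission.

    ``measurements`` and ``exposures`` hold only this patient's events
    (columns ``time_h, analyte, value`` and ``time_h, exposure``), sorted by
    time.  ``onset_time`` is the detected AKI onset in hours (None when no
    event); ``patient`` supplies demographics and the RRT/death times.
    """
    pat = dict(patient)
    mt = measurements["time_h"].to_numpy(dtype=float)
    if mt.size > 1 and np.any(np.diff(mt) < 0):
        raise AkiPredictError(f"unsorted measurements for patient {pat.get('patient_id')!r}")

    event_times = np.unique(
        np.concatenate([mt, exposures["time_h"].to_numpy(dtype=float)])
    )
    if onset_time is not None and np.isfinite(onset_time):
        event_times = event_times[event_times < onset_time - EPS]
    else:
        onset_time = None
    nrow = event_times.size
    out: dict[str, np.ndarray] = {
        "patient_id": np.repeat(pat["patient_id"], nrow),
        "time_h": event_times,
    }
    for c in _DEMO_COLS:
        out[c] = np.repeat(float(pat[c]), nrow)

    by_analyte = {a: g for a, g in measurements.groupby("analyte", sort=False)}
    for a in _CARRIED_LABS:
        if a in by_analyte:
            g = by_analyte[a]
            out[a] = _locf(
                g["time_h"].to_numpy(dtype=float), g["value"].to_numpy(dtype=float), event_times
            )
        else:
            out[a] = np.full(nrow, np.nan)

    if "creatinine" in by_analyte:
        g = by_analyte["creatinine"]
        ct = g["time_h"].to_numpy(dtype=float)
        cv = g["value"].to_numpy(dtype=float)
        last = _locf(ct, cv, event_times)
        baseline = _window_min_exclusive(ct, cv, event_times, BASELINE_WINDOW_H)
        min48 = _window_min_exclusive(ct, cv, event_times, ABSOLUTE_WINDOW_H)
        delta = last - min48
        delta[np.isnan(min48) & ~np.isnan(last)] = 0.0
    else:
        last = baseline = delta = np.full(nrow, np.nan)
    out["last_creatinine"] = last
    out["baseline_creatinine"] = baseline
    out["delta_creatinine_48h"] = delta

    exp_on = dict(zip(exposures["exposure"], exposures["time_h"]))
    for name in EXPOSURES:
        t_on = exp_on.get(name, np.inf)
        out[name] = (event_times >= t_on - EPS).astype(float)

    rrt_time = pat.get("rrt_time_h")
    death_time = pat.get("death_time_h")
    sustained_time = onset_time if (onset_time is not None and sustained) else None
    out["label_aki_24h"] = label_rows(event_times, onset_time, horizon)
    out["label_sustained_aki_24h"] = label_rows(event_times, sustained_time, horizon)
    out["label_rrt_24h"] = label_rows(event_times, _as_time(rrt_time), horizon)
    out["label_death_24h"] = label_rows(event_times, _as_time(death_time), horizon)
    out["aki_any"] = np.repeat(int(onset_time is not None), nrow)
    out["sustained_any"] = np.repeat(int(sustained_time is not None), nrow)
    out["rrt_any"] = np.repeat(int(_as_time(rrt_time) is not None), nrow)
    out["death_any"] = np.repeat(int(_as_time(death_time) is not None), nrow)
    return pd.DataFrame(out)


def _as_time(value) -> float | None:
    if value is None:
        return None
    value = float(value)
    return value if np.isfinite(value) else None


def build_matrix(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    exposures: pd.DataFrame,
    events: pd.DataFrame,
    horizon: float = DEFAULT_HORIZON_H,
) -> pd.DataFrame:
    """Build observation rows for a whole cohort.

    ``events`` is the KDIGO detection output (``patient_id, onset_time_h,
    sustained``); patients absent from it contribute fully uncensored rows.
    """
    ev = events.set_index("patient_id") if len(events) else pd.DataFrame()
    meas_by_pid = dict(tuple(measurements.groupby("patient_id", sort=False)))
    exp_by_pid = dict(tuple(exposures.groupby("patient_id", sort=False)))
    empty_meas = measurements.iloc[0:0]
    empty_exp = exposures.iloc[0:0]
    frames = []
    for _, pat in patients.iterrows():
        pid = pat["patient_id"]
        onset, sustained = None, False
        if len(ev) and pid in ev.index:
            onset = float(ev.loc[pid, "onset_time_h"])
            sustained = bool(ev.loc[pid, "sustained"])
        frames.append(
            build_rows(
                pat,
                meas_by_pid.get(pid, empty_meas),
                exp_by_pid.get(pid, empty_exp),
                onset_time=onset,
                sustained=sustained,
                horizon=horizon,
            )
        )
    return pd.concat(frames, ignore_index=True)


def complete_case_filter(
    rows: pd.DataFrame, model_class: str
) -> tuple[pd.DataFrame, float]:
    """Drop rows missing any covariate required by ``model_class``.

    Returns the filtered rows and the dropped fraction.  Demographics are
    complete by construction, so the demographic class drops nothing.
    """
    required = list(class_covariates(model_class))
    keep = ~rows[required].isna().any(axis=1)
    dropped = 1.0 - (keep.sum() / len(rows)) if len(rows) else 0.0
    return rows.loc[keep].reset_index(drop=True), float(dropped)


def split_cohort(
    patients: pd.DataFrame,
    fractions: tuple[float, float] = (2 / 3, 1 / 3),
    seed: int = 0,
    internal_hospital: str = "H1",
) -> pd.Series:
    """Patient-level train/validation split at the internal hospital.

    Patients at ``internal_hospital`` are randomly assigned to ``train`` and
    ``validation`` in the given proportions (largest-remainder rounding, so a
    9-patient cohort at (2/3, 1/3) splits exactly 6/3); patients at other
    hospitals keep their hospital id as an external-validation stratum.
    Deterministic under a fixed seed; never splits within a patient.
    """
    if len(fractions) != 2 or not np.isclose(sum(fractions), 1.0) or min(fractions) < 0:
        raise ConfigurationError(f"fractions must be two nonnegative values summing to 1")
    rng = np.random.default_rng(seed)
    part = pd.Series(index=patients["patient_id"], dtype=object, name="partition")
    internal = patients.loc[patients["hospital"] == internal_hospital, "patient_id"].to_numpy()
    external = patients.loc[patients["hospital"] != internal_hospital]
    perm = rng.permutation(internal)
    n_train = int(np.floor(fractions[0] * len(internal) + 0.5))
    part.loc[perm[:n_train]] = "train"
    part.loc[perm[n_train:]] = "validation"
    part.loc[external["patient_id"]] = external["hospital"].to_numpy()
    return part
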