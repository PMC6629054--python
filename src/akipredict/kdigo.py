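"""KDIGO creatinine-criteria AKI detection, staging, and sustained-AKI flagging.

AKI is detected from the inpatient serum-creatinine series alone (urine-output
criteria are not used): onset is the earliest measurement at which either

* the value has risen by >= 0.3 mg/dL above the minimum value observed in the
  preceding 48 hours (absolute criterion), or
* the value is >= 1.5x the rolling baseline, defined as the lowest creatinine
  observed in the preceding 7 days (relative criterion).

Both look-back windows are half-open — ``[t - w, t)`` — so the triggering
measurement is never compared against itself, and onset requires at least one
strictly earlier measurement: AKI cannot be declared until a patient has two
measured creatinine values.  Only the first event per admission is detected;
everything after onset is censored by downstream modeling.

Staging follows the KDIGO guideline thresholds: stage 3 at >= 3.0x baseline or
an absolute value >= 4.0 mg/dL (with onset criteria met), stage 2 at >= 2.0x
baseline, stage 1 otherwise.  Sustained AKI requires the onset measurement and
the next measurement to each satisfy the trigger against their own windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AkiPredictError

#: Detection constants (mg/dL, hours, unitless ratio).
ABSOLUTE_RISE_MG_DL = 0.3
ABSOLUTE_WINDOW_H = 48.0
RELATIVE_RISE_RATIO = 1.5
BASELINE_WINDOW_H = 168.0

#: Staging thresholds from the KDIGO guideline.
STAGE2_RATIO = 2.0
STAGE3_RATIO = 3.0
STAGE3_ABSOLUTE_MG_DL = 4.0

#: Tolerance on mg/dL comparisons so float representation never flips a
#: decision at exactly 0.3 or exactly 1.5x.
EPS = 1e-9


@dataclass(frozen=True)
class CreatinineSeries:
    """Ordered inpatient creatinine series for one admission.

    Times are hours from admission and must be strictly increasing after
    collapsing simultaneous duplicates (which collapse to their maximum value,
    a deterministic and detection-conservative choice); values are mg/dL > 0.
    """

    patient_id: str
    times: np.ndarray
    values: np.ndarray

    @classmethod
    def from_pairs(cls, patient_id, pairs: Sequence[tuple[float, float]]) -> "CreatinineSeries":
        if len(pairs) == 0:
            raise AkiPredictError(f"empty creatinine series for patient {patient_id!r}")
        t = np.asarray([p[0] for p in pairs], dtype=float)
        v = np.asarray([p[1] for p in pairs], dtype=float)
        return cls.from_arrays(patient_id, t, v)

    @classmethod
    def from_arrays(cls, patient_id, times, values) -> "CreatinineSeries":
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.size == 0:
            raise AkiPredictError(f"empty creatinine series for patient {patient_id!r}")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise AkiPredictError(
                f"non-positive or non-finite creatinine value for patient {patient_id!r}"
            )
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        # collapse simultaneous duplicates to the maximum value
        if t.size > 1 and np.any(np.diff(t) == 0):
            keep_t, keep_v = [t[0]], [v[0]]
            for ti, vi in zip(t[1:], v[1:]):
                if ti == keep_t[-1]:
                    keep_v[-1] = max(keep_v[-1], vi)
                else:
                    keep_t.append(ti)
                    keep_v.append(vi)
            t, v = np.asarray(keep_t), np.asarray(keep_v)
        obj = cls(patient_id, t, v)
        return obj

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class AkiEvent:
    """A detected AKI onset.

    ``criterion`` records which trigger fired at onset: the 48-hour absolute
    rise, the 1.5x-baseline relative rise, or both simultaneously.
    ``baseline_at_onset`` is the 7-day rolling-baseline minimum at onset time
    (NaN when no prior value exists in the baseline window, which can only
    happen when the absolute criterion alone fired).
    """

    patient_id: str
    onset_time: float
    stage: int
    criterion: str  # "absolute_rise_48h" | "relative_rise_baseline" | "both"
    baseline_at_onset: float
    sustained: bool


def rolling_baseline(series: CreatinineSeries, t: float) -> float:
    """Lowest creatinine in the half-open 7-day window ``[t - 168h, t)``.

    Returns NaN when no measurement falls in the window (the baseline is
    undefined, not zero).
    """
    if len(series) == 0:  # pragma: no cover - constructor forbids this
        raise AkiPredictError("empty creatinine series")
    return _window_min(series.times, series.values, t, BASELINE_WINDOW_H)


def _window_min(times: np.ndarray, values: np.ndarray, t: float, window_h: float) -> float:
    """Min of values with times in ``[t - window_h, t)``; NaN if empty."""
    lo = np.searchsorted(times, t - window_h - EPS, side="left")
    hi = np.searchsorted(times, t, side="left")
    if hi <= lo:
        return math.nan
    return float(values[lo:hi].min())


def _trigger_at(series: CreatinineSeries, i: int) -> Optional[str]:
    """Which KDIGO criterion fires at measurement index ``i``; None if none."""
    t = float(series.times[i])
    v = float(series.values[i])
    min48 = _window_min(series.times, series.values, t, ABSOLUTE_WINDOW_H)
    base = _window_min(series.times, series.values, t, BASELINE_WINDOW_H)
    abs_fires = not math.isnan(min48) and (v - min48) >= ABSOLUTE_RISE_MG_DL - EPS
    rel_fires = not math.isnan(base) and v >= RELATIVE_RISE_RATIO * base - EPS
    if abs_fires and rel_fires:
        return "both"
    if abs_fires:
        return "absolute_rise_48h"
    if rel_fires:
        return "relative_rise_baseline"
    return None


def stage_aki(value: float, baseline: float) -> int:
    """KDIGO stage of a triggering creatinine ``value`` against ``baseline``.

    Stage boundaries are inclusive at their lower edge (a value exactly 2.0x
    baseline is stage 2).  Requires positive inputs.
    """
    if not (value > 0) or not (baseline > 0):
        raise AkiPredictError("stage_aki requires positive value and baseline")
    ratio = value / baseline
    if ratio >= STAGE3_RATIO - EPS or value >= STAGE3_ABSOLUTE_MG_DL - EPS:
        return 3
    if ratio >= STAGE2_RATIO - EPS:
        return 2
    return 1


def _stage_at(series: CreatinineSeries, i: int) -> int:
    """Stage at measurement index ``i`` (onset criteria already met there)."""
    v = float(series.values[i])
    base = _window_min(series.times, series.values, float(series.times[i]), BASELINE_WINDOW_H)
    if math.isnan(base):
        # Absolute criterion fired with no value inside the 7-day window
        # (impossible in practice: the 48h window is a subset of the 7-day
        # window) — stage on the absolute threshold only.
        return 3 if v >= STAGE3_ABSOLUTE_MG_DL - EPS else 1
    return stage_aki(v, base)


def flag_sustained(series: CreatinineSeries, event: "AkiEvent") -> bool:
    """True iff the onset measurement and the next one both satisfy a trigger.

    Each measurement is evaluated against its own look-back windows.  False
    when the onset is the last measurement of the admission.
    """
    idx = np.flatnonzero(np.isclose(series.times, event.onset_time, rtol=0, atol=EPS))
    if idx.size == 0:
        raise AkiPredictError(
            f"event onset time {event.onset_time} is not a measurement time for "
            f"patient {series.patient_id!r}"
        )
    i = int(idx[0])
    if i + 1 >= len(series):
        return False
    return _trigger_at(series, i + 1) is not None


def detect_aki(series: CreatinineSeries) -> Optional[AkiEvent]:
    """Detect the first AKI onset in an admission's creatinine series.

    Scans measurements in time order; the first one (with at least one
    strictly earlier measurement) at which either KDIGO creatinine criterion
    fires is the onset.  Returns None when no measurement triggers.
    """
    for i in range(1, len(series)):
        crit = _trigger_at(series, i)
        if crit is None:
            continue
        t = float(series.times[i])
        base = _window_min(series.times, series.values, t, BASELINE_WINDOW_H)
        event = AkiEvent(
            patient_id=series.patient_id,
            onset_time=t,
            stage=_stage_at(series, i),
            criterion=crit,
            baseline_at_onset=base,
            sustained=False,
        )
        sustained = flag_sustained(series, event)
        return AkiEvent(**{**event.__dict__, "sustained": sustained})
    return None


def detect_aki_table(measurements, patient_col: str = "patient_id"):
    """Run :func:`detect_aki` per patient over a long measurement table.

    ``measurements`` needs columns ``patient_id, time_h, analyte, value``;
    only ``analyte == "creatinine"`` rows are used.  Returns a DataFrame with
    one row per detected event (patients without creatinine rows or without
    an event are absent).
    """
    import pandas as pd

    creat = measurements[measurements["analyte"] == "creatinine"]
    records = []
    for pid, grp in creat.groupby(patient_col, sort=True):
        series = CreatinineSeries.from_arrays(
            pid, grp["time_h"].to_numpy(), grp["value"].to_numpy()
        )
        ev = detect_aki(series)
        if ev is not None:
            records.append(
                {
                    "patient_id": pid,
                    "onset_time_h": ev.onset_time,
                    "stage": ev.stage,
                    "criterion": ev.criterion,
                    "baseline_at_onset": ev.baseline_at_onset,
                    "sustained": ev.sustained,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "patient_id",
            "onset_time_h",
            "stage",
            "criterion",
            "baseline_at_onset",
            "sustained",
        ],
    )
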