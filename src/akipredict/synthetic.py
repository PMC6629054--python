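"""Synthetic inpatient EHR generator with a known discrete-time AKI hazard.

The generator emulates the longitudinal structure the downstream analysis
assumes: irregularly sampled laboratory panels on a Poisson schedule,
carry-forward covariate semantics, absorbing medication/procedure exposures,
per-hospital heterogeneity in AKI incidence, and episodic creatinine rises
after onset so the KDIGO engine can rediscover the generated events.

AKI onsets are drawn from a discrete-time logistic hazard evaluated on a
fixed 6-hour grid: at each tick the event probability is
``expit(intercept + hospital_effect + sum(coef * covariate_state))`` over the
configured hazard covariates (demographics, current laboratory state, and
exposure indicators).  The full person-period frame — true covariate states,
per-tick event probability, and the realized event indicator — is returned as
ground truth, which makes parameter-recovery experiments direct: a logistic
fit on that frame estimates exactly the generative coefficients.

Exclusion-eligible patients (missing discharge time, fewer than two
creatinine values, ESKD codes, admission creatinine >= 4 mg/dL) are generated
deliberately so the cohort filter has work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit

from .covariates import DEMOGRAPHICS, EXPOSURES, LAB_ANALYTES
from .errors import ConfigurationError

#: Population distributions for non-creatinine analytes:
#: name -> (population mean, between-patient sd, within-patient sd, floor).
LAB_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "bicarbonate": (23.0, 3.0, 1.5, 5.0),
    "bun": (18.0, 8.0, 3.0, 2.0),
    "chloride": (102.0, 4.0, 2.0, 70.0),
    "hemoglobin": (12.4, 2.0, 0.5, 3.0),
    "platelets": (230.0, 80.0, 20.0, 10.0),
    "potassium": (4.1, 0.45, 0.25, 1.5),
    "sodium": (138.0, 4.0, 2.0, 110.0),
    "wbc": (9.5, 3.5, 1.5, 0.5),
}

#: Ever-exposed prevalence per admission for medications and procedures,
#: loosely matching a general inpatient population.
DEFAULT_EXPOSURE_PREVALENCES: dict[str, float] = {
    "ace_arb": 0.21,
    "antibiotic": 0.60,
    "chemotherapy": 0.02,
    "diuretic": 0.27,
    "narcotic": 0.60,
    "nsaid": 0.10,
    "vasopressor": 0.17,
    "proton_pump_inhibitor": 0.39,
    "statin": 0.19,
    "bipap": 0.033,
    "contrast_study": 0.21,
    "ventilation": 0.07,
    "icu": 0.18,
    "cardiac_catheterization": 0.045,
    "rbc_transfusion": 0.12,
}

#: Demographic prevalences / distributions used by the generator.
DEMOGRAPHIC_PARAMS = {
    "sex_male": 0.47,
    "race_black": 0.18,
    "surgical_admission": 0.26,
    "chf": 0.15,
    "hypertension": 0.09,
    "diabetes": 0.22,
    "liver_disease": 0.07,
}

#: Covariate names a generative hazard may reference.
HAZARD_ELIGIBLE = tuple(DEMOGRAPHICS) + tuple(
    a for a in LAB_ANALYTES if a != "creatinine"
) + tuple(EXPOSURES)


class AkiRiseProfile(BaseModel):
    """Post-onset creatinine escalation: linear rise, then plateau."""

    slope_mg_dl_per_24h: float = Field(default=0.8, gt=0)
    duration_hours: float = Field(default=72.0, gt=0)


class SimConfig(BaseModel):
    """Generator configuration; the defaults define the study conditions.

    The default hazard puts weight on BUN, bicarbonate, heart failure, ICU
    transfer, and diuretic exposure, with an intercept calibrated so that a
    median-length admission carries roughly a 15–20% AKI risk at the
    reference hospital, matching a general hospitalized population.
    """

    n_patients: int = Field(default=1000, ge=1)
    seed: int = 0
    mean_los_hours: float = Field(default=120.0, gt=0)
    min_los_hours: float = Field(default=24.0, gt=0)
    tick_hours: float = Field(default=6.0, gt=0)
    lab_rate_per_day: float = Field(default=2.0, gt=0)
    baseline_creat_log_mean: float = float(np.log(0.9))
    baseline_creat_log_sd: float = Field(default=0.25, gt=0)
    creat_noise_log_sd: float = Field(default=0.03, gt=0)
    hazard_intercept: float = -4.4
    hazard_coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "age": 0.015,
            "bun": 0.03,
            "bicarbonate": -0.08,
            "chf": 0.6,
            "icu": 0.7,
            "diuretic": 0.45,
        }
    )
    aki_rise_profile: AkiRiseProfile = Field(default_factory=AkiRiseProfile)
    exposure_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_EXPOSURE_PREVALENCES)
    )
    hospital_effects: dict[str, float] = Field(
        default_factory=lambda: {"H1": 0.0, "H2": -0.15, "H3": -0.6}
    )
    hospital_weights: dict[str, float] = Field(
        default_factory=lambda: {"H1": 0.54, "H2": 0.26, "H3": 0.20}
    )
    # Deliberate exclusion-eligible fractions.
    p_missing_discharge: float = Field(default=0.02, ge=0, le=1)
    p_eskd: float = Field(default=0.02, ge=0, le=1)
    p_high_admission_creatinine: float = Field(default=0.01, ge=0, le=1)
    p_sparse_labs: float = Field(default=0.02, ge=0, le=1)
    # Secondary outcomes.
    rrt_prob_given_aki: float = Field(default=0.05, ge=0, le=1)
    death_prob_base: float = Field(default=0.02, ge=0, le=1)
    death_prob_aki_extra: float = Field(default=0.05, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in self.hazard_coefficients:
            if name not in HAZARD_ELIGIBLE:
                raise ConfigurationError(
                    f"hazard_coefficients: {name!r} is not a hazard-eligible covariate"
                )
        for name, p in self.exposure_prevalences.items():
            if name not in EXPOSURES:
                raise ConfigurationError(f"exposure_prevalences: unknown exposure {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(
                    f"exposure_prevalences: probability for {name!r} outside [0, 1]"
                )
        if set(self.hospital_weights) != set(self.hospital_effects):
            raise ConfigurationError("hospital_weights and hospital_effects must share keys")
        if not np.isclose(sum(self.hospital_weights.values()), 1.0):
            raise ConfigurationError("hospital_weights must sum to 1")
        if self.min_los_hours >= self.mean_los_hours:
            raise ConfigurationError("min_los_hours must be below mean_los_hours")
        return self


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must rediscover.

    ``onsets`` has one row per patient with a true AKI onset (hours from
    admission).  ``person_period`` is the discrete-time frame the hazard was
    evaluated on: one row per 6-hour tick up to and including the event tick,
    with the true covariate states, the true per-tick event probability, and
    the realized event indicator.  ``coefficients``/``intercept`` are the
    generative log-odds.
    """

    onsets: pd.DataFrame
    person_period: pd.DataFrame
    coefficients: dict[str, float]
    intercept: float
    hospital_effects: dict[str, float] = field(default_factory=dict)


def _locf_at(
    query_pid: np.ndarray,
    query_t: np.ndarray,
    obs_pid: np.ndarray,
    obs_t: np.ndarray,
    obs_v: np.ndarray,
    fallback: np.ndarray,
    key_scale: float,
) -> np.ndarray:
    """Vectorized last-observation-carried-forward across many patients.

    Both (pid, t) streams must be sorted by pid then time; ``fallback`` is a
    per-patient value used before the first observation.
    """
    obs_key = obs_pid * key_scale + obs_t
    query_key = query_pid * key_scale + query_t
    idx = np.searchsorted(obs_key, query_key, side="right") - 1
    valid = (idx >= 0) & (obs_pid[np.clip(idx, 0, None)] == query_pid)
    out = fallback[query_pid].astype(float).copy()
    out[valid] = obs_v[idx[valid]]
    return out


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic hospital cohort.

    Returns ``(patients, measurements, exposures, ground_truth)`` with times
    in hours from admission.  Fixing the config (including the seed) makes the
    output bit-identical across runs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    pid_index = np.arange(n)

    hospitals = sorted(cfg.hospital_weights)
    hosp_w = np.array([cfg.hospital_weights[h] for h in hospitals])
    hosp_idx = rng.choice(len(hospitals), size=n, p=hosp_w / hosp_w.sum())
    hosp_eff = np.array([cfg.hospital_effects[h] for h in hospitals])[hosp_idx]

    los = cfg.min_los_hours + rng.exponential(cfg.mean_los_hours - cfg.min_los_hours, n)

    demo = {
        "age": np.clip(rng.normal(62.0, 16.0, n), 18.0, 100.0).round(0),
        "elixhauser": rng.poisson(3.0, n).astype(float),
    }
    for name, p in DEMOGRAPHIC_PARAMS.items():
        demo[name] = (rng.random(n) < p).astype(float)

    missing_discharge = rng.random(n) < cfg.p_missing_discharge
    eskd = rng.random(n) < cfg.p_eskd
    high_creat = rng.random(n) < cfg.p_high_admission_creatinine
    sparse_labs = rng.random(n) < cfg.p_sparse_labs

    baseline_creat = np.exp(
        rng.normal(cfg.baseline_creat_log_mean, cfg.baseline_creat_log_sd, n)
    )
    baseline_creat[high_creat] = rng.uniform(4.5, 7.0, int(high_creat.sum()))

    lab_means = {
        a: np.maximum(mu + bsd * rng.normal(size=n), floor)
        for a, (mu, bsd, _, floor) in LAB_DISTRIBUTIONS.items()
    }

    # --- laboratory panel schedule: one admission panel plus a Poisson stream
    n_extra = rng.poisson(cfg.lab_rate_per_day * los / 24.0)
    n_extra[sparse_labs] = 0
    total_extra = int(n_extra.sum())
    extra_pid = np.repeat(pid_index, n_extra)
    extra_t = rng.uniform(1.0, np.repeat(los, n_extra) - 0.5)
    panel_pid = np.concatenate([pid_index, extra_pid])
    panel_t = np.concatenate([np.full(n, 0.5), extra_t])
    order = np.lexsort((panel_t, panel_pid))
    panel_pid, panel_t = panel_pid[order], panel_t[order]
    key_scale = float(panel_t.max() if panel_t.size else 1.0) + cfg.mean_los_hours * 100

    # --- absorbing exposures: onset time per (patient, exposure)
    exp_names = sorted(cfg.exposure_prevalences)
    exposure_onset: dict[str, np.ndarray] = {}
    for name in exp_names:
        ever = rng.random(n) < cfg.exposure_prevalences[name]
        t_on = rng.uniform(1.0, los)
        t_on[~ever] = np.inf
        exposure_onset[name] = t_on

    # --- non-creatinine panel values (creatinine depends on onset, done later)
    panel_values: dict[str, np.ndarray] = {}
    for a, (_, _, wsd, floor) in LAB_DISTRIBUTIONS.items():
        panel_values[a] = np.maximum(
            lab_means[a][panel_pid] + wsd * rng.normal(size=panel_pid.size), floor
        )

    # --- discrete-time hazard on the tick grid
    n_ticks = np.floor(los / cfg.tick_hours).astype(int)
    tick_pid = np.repeat(pid_index, n_ticks)
    offsets = np.concatenate([[0], np.cumsum(n_ticks)])
    tick_t = (np.arange(n_ticks.sum()) - offsets[tick_pid] + 1) * cfg.tick_hours

    lp = np.full(tick_pid.size, cfg.hazard_intercept) + hosp_eff[tick_pid]
    state_cols: dict[str, np.ndarray] = {}
    for name, coef in sorted(cfg.hazard_coefficients.items()):
        if name in DEMOGRAPHICS:
            state = demo[name][tick_pid]
        elif name in LAB_DISTRIBUTIONS:
            state = _locf_at(
                tick_pid, tick_t, panel_pid, panel_t,
                panel_values[name], lab_means[name], key_scale,
            )
        else:  # exposure indicator
            state = (tick_t >= exposure_onset[name][tick_pid]).astype(float)
        state_cols[name] = state
        lp += coef * state
    true_p = expit(lp)

    u = rng.random(tick_pid.size)
    fires = u < true_p
    fire_idx = np.flatnonzero(fires)
    first_fire_pid, first_pos = np.unique(tick_pid[fire_idx], return_index=True)
    first_fire_idx = fire_idx[first_pos]
    onset_time = np.full(n, np.inf)
    onset_time[first_fire_pid] = tick_t[first_fire_idx]

    # person-period rows are censored after the event tick
    keep = tick_t <= onset_time[tick_pid]
    person_period = pd.DataFrame({"patient_id": tick_pid[keep], "time_h": tick_t[keep]})
    for name, state in state_cols.items():
        person_period[name] = state[keep]
    person_period["true_p"] = true_p[keep]
    person_period["event"] = (tick_t[keep] == onset_time[tick_pid[keep]]).astype(int)

    # --- creatinine values: lognormal jitter around baseline, post-onset rise
    creat = baseline_creat[panel_pid] * np.exp(
        cfg.creat_noise_log_sd * rng.normal(size=panel_pid.size)
    )
    dt_post = panel_t - onset_time[panel_pid]
    rising = dt_post > 0
    rise = (
        cfg.aki_rise_profile.slope_mg_dl_per_24h
        * np.minimum(dt_post, cfg.aki_rise_profile.duration_hours)
        / 24.0
    )
    creat[rising] += rise[rising]
    panel_values["creatinine"] = creat

    # --- secondary outcomes
    has_onset = np.isfinite(onset_time)
    rrt = has_onset & (rng.random(n) < cfg.rrt_prob_given_aki)
    rrt_time = np.where(
        rrt, np.minimum(onset_time + rng.uniform(6.0, 48.0, n), los - 0.5), np.nan
    )
    p_death = cfg.death_prob_base + cfg.death_prob_aki_extra * has_onset
    died = rng.random(n) < p_death
    death_time = np.where(died, rng.uniform(0.7 * los, los), np.nan)

    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in pid_index],
            "hospital": [hospitals[i] for i in hosp_idx],
            "los_hours": los,
            "discharge_time_h": np.where(missing_discharge, np.nan, los),
            "eskd": eskd,
            **{k: demo[k] for k in DEMOGRAPHICS},
            "rrt_time_h": rrt_time,
            "death_time_h": death_time,
        }
    )

    pid_str = np.array(patients["patient_id"])
    meas_frames = []
    for a in LAB_ANALYTES:
        meas_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid_str[panel_pid],
                    "time_h": panel_t,
                    "analyte": a,
                    "value": panel_values[a],
                }
            )
        )
    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        .sort_values(["patient_id", "time_h", "analyte"], kind="stable")
        .reset_index(drop=True)
    )

    exp_records = []
    for name in exp_names:
        t_on = exposure_onset[name]
        mask = np.isfinite(t_on)
        exp_records.append(
            pd.DataFrame(
                {
                    "patient_id": pid_str[pid_index[mask]],
                    "time_h": t_on[mask],
                    "exposure": name,
                }
            )
        )
    exposures = (
        pd.concat(exp_records, ignore_index=True)
        .sort_values(["patient_id", "time_h", "exposure"], kind="stable")
        .reset_index(drop=True)
    )

    # analytic per-patient event probability over the whole (uncensored) stay:
    # 1 - prod(1 - p_tick), computed before any censoring
    log_surv = np.zeros(n)
    np.add.at(log_surv, tick_pid, np.log1p(-true_p))
    patient_event_prob = 1.0 - np.exp(log_surv)

    onsets = pd.DataFrame(
        {
            "patient_id": pid_str,
            "onset_time_h": np.where(has_onset, onset_time, np.nan),
            "true_event_prob": patient_event_prob,
        }
    )
    person_period["patient_id"] = pid_str[person_period["patient_id"].to_numpy()]
    truth = GroundTruth(
        onsets=onsets,
        person_period=person_period,
        coefficients=dict(sorted(cfg.hazard_coefficients.items())),
        intercept=cfg.hazard_intercept,
        hospital_effects=dict(cfg.hospital_effects),
    )
    return patients, measurements, exposures, truth


def inject_missingness(
    measurements: pd.DataFrame, rate: float, seed: int
) -> pd.DataFrame:
    """Remove a ``rate`` fraction of non-creatinine laboratory rows at random.

    Creatinine rows are never removed: the outcome must stay ascertainable.
    Deterministic under a fixed seed.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError(f"missingness rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    droppable = (measurements["analyte"] != "creatinine").to_numpy()
    drop = droppable & (rng.random(len(measurements)) < rate)
    return measurements.loc[~drop].reset_index(drop=True)
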