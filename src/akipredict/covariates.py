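"""Covariate registry: names, classes, and temporal kinds.

The model covariates fall into five classes — demographics (time-invariant),
laboratory values, medications, procedures, and the 48-hour creatinine delta,
which is modeled both inside the laboratory model and as a model of its own
because of its outsized predictive strength.  Each covariate appears exactly
once in the registry; model classes are defined on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

CovariateClass = Literal[
    "demographic", "laboratory", "medication", "procedure", "delta_creatinine"
]
CovariateKind = Literal[
    "time_invariant", "carried_forward_numeric", "carried_forward_binary", "derived"
]


@dataclass(frozen=True)
class CovariateSpec:
    """One model covariate: its name, covariate class, and temporal behavior."""

    name: str
    covariate_class: CovariateClass
    kind: CovariateKind


DEMOGRAPHICS: tuple[str, ...] = (
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

#: Laboratory analytes measured as timed events (raw measurement names).
LAB_ANALYTES: tuple[str, ...] = (
    "creatinine",
    "bicarbonate",
    "bun",
    "chloride",
    "hemoglobin",
    "potassium",
    "sodium",
    "wbc",
    "platelets",
)

#: Laboratory covariates as they enter the model.  Raw creatinine enters via
#: three derived features: the carried-forward last value, the 7-day rolling
#: baseline, and the 48-hour delta.
LAB_COVARIATES: tuple[str, ...] = (
    "bicarbonate",
    "bun",
    "chloride",
    "baseline_creatinine",
    "last_creatinine",
    "hemoglobin",
    "potassium",
    "sodium",
    "wbc",
    "platelets",
)

MEDICATIONS: tuple[str, ...] = (
    "ace_arb",
    "antibiotic",
    "chemotherapy",
    "diuretic",
    "narcotic",
    "nsaid",
    "vasopressor",
    "proton_pump_inhibitor",
    "statin",
)

PROCEDURES: tuple[str, ...] = (
    "bipap",
    "contrast_study",
    "ventilation",
    "icu",
    "cardiac_catheterization",
    "rbc_transfusion",
)

DELTA_CREATININE = "delta_creatinine_48h"

EXPOSURES: tuple[str, ...] = MEDICATIONS + PROCEDURES

REGISTRY: tuple[CovariateSpec, ...] = (
    tuple(CovariateSpec(n, "demographic", "time_invariant") for n in DEMOGRAPHICS)
    + tuple(
        CovariateSpec(
            n,
            "laboratory",
            "derived" if n in ("baseline_creatinine", "last_creatinine") else "carried_forward_numeric",
        )
        for n in LAB_COVARIATES
    )
    + tuple(CovariateSpec(n, "medication", "carried_forward_binary") for n in MEDICATIONS)
    + tuple(CovariateSpec(n, "procedure", "carried_forward_binary") for n in PROCEDURES)
    + (CovariateSpec(DELTA_CREATININE, "delta_creatinine", "derived"),)
)

ALL_COVARIATES: tuple[str, ...] = tuple(s.name for s in REGISTRY)

#: Covariates required by each model class.  The laboratory model includes the
#: 48-hour creatinine delta (it is a laboratory-derived quantity); the delta is
#: additionally modeled on its own because of its strong marginal performance.
MODEL_CLASSES: dict[str, tuple[str, ...]] = {
    "full": ALL_COVARIATES,
    "demographic": DEMOGRAPHICS,
    "medications": MEDICATIONS,
    "procedures": PROCEDURES,
    "laboratory": LAB_COVARIATES + (DELTA_CREATININE,),
    "change_in_creatinine": (DELTA_CREATININE,),
}

#: Outcome tag -> label column in the observation matrix.
OUTCOME_LABELS: dict[str, str] = {
    "aki24": "label_aki_24h",
    "sustained_aki24": "label_sustained_aki_24h",
    "rrt": "label_rrt_24h",
    "death": "label_death_24h",
}


def class_covariates(model_class: str) -> tuple[str, ...]:
    """Covariates required by ``model_class``; raises on unknown class."""
    try:
        return MODEL_CLASSES[model_class]
    except KeyError:
        raise ValueError(
            f"unknown model class {model_class!r}; expected one of {sorted(MODEL_CLASSES)}"
        ) from None
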