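"""End-to-end pipeline driver: simulate -> filter -> label -> build -> fit -> evaluate.

Every run is fully determined by its :class:`PipelineConfig` (all randomness
flows from named seeds); the manifest written at the end records input file
hashes, the config, per-stage row/patient counts, and the package version, so
any output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import apply_exclusions
from .covariates import MODEL_CLASSES, OUTCOME_LABELS
from .discretize import build_matrix, complete_case_filter, split_cohort
from .errors import (
    AkiPredictError,
    ConfigurationError,
    SeparationError,
    SingularDesignError,
)
from .evaluation import evaluation_grid, grid_to_table, plot_roc_panels
from .io import read_cohort, write_cohort
from .kdigo import detect_aki_table
from .model import fit_discrete_logit
from .synthetic import SimConfig, generate_cohort, inject_missingness


class PipelineConfig(BaseModel):
    """Configuration for a full pipeline run."""

    out_dir: str = "pipeline_out"
    sim: SimConfig = Field(default_factory=SimConfig)
    missingness_rate: float = Field(default=0.08, ge=0, le=1)
    horizon_hours: float = Field(default=24.0, gt=0)
    split_fractions: tuple[float, float] = (2 / 3, 1 / 3)
    split_seed: int = 0
    internal_hospital: str = "H1"
    bootstrap_B: int = Field(default=500, ge=100)
    eval_seed: int = 0
    model_classes: list[str] = Field(default_factory=lambda: list(MODEL_CLASSES))
    outcomes: list[str] = Field(default_factory=lambda: list(OUTCOME_LABELS))
    make_plots: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the manifest."""
    for mc in config.model_classes:
        if mc not in MODEL_CLASSES:
            raise ConfigurationError(f"unknown model class {mc!r}")
    for oc in config.outcomes:
        if oc not in OUTCOME_LABELS:
            raise ConfigurationError(f"unknown outcome {oc!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "inputs": {},
    }

    # --- simulate
    patients, measurements, exposures, truth = generate_cohort(config.sim)
    measurements = inject_missingness(
        measurements, config.missingness_rate, seed=config.sim.seed + 1
    )
    paths = write_cohort(out / "cohort", patients, measurements, exposures, truth)
    manifest["inputs"] = {k: _sha256(Path(v)) for k, v in paths.items()}
    manifest["stages"]["simulate"] = {
        "n_patients": len(patients),
        "n_measurements": len(measurements),
        "n_exposures": len(exposures),
    }

    # --- filter (cohort exclusions)
    patients_io, measurements_io, exposures_io = read_cohort(out / "cohort")
    included, report = apply_exclusions(patients_io, measurements_io)
    with open(out / "exclusion_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    manifest["stages"]["filter"] = report.to_dict()
    meas = measurements_io[measurements_io["patient_id"].isin(included["patient_id"])]
    exp = exposures_io[exposures_io["patient_id"].isin(included["patient_id"])]

    # --- label (KDIGO detection)
    events = detect_aki_table(meas)
    events.to_csv(out / "events.csv", index=False)
    manifest["stages"]["label"] = {
        "n_events": len(events),
        "n_sustained": int(events["sustained"].sum()) if len(events) else 0,
    }

    # --- build (observation matrix)
    matrix = build_matrix(included, meas, exp, events, horizon=config.horizon_hours)
    part = split_cohort(
        included,
        fractions=config.split_fractions,
        seed=config.split_seed,
        internal_hospital=config.internal_hospital,
    )
    matrix["partition"] = part.loc[matrix["patient_id"]].to_numpy()
    matrix.to_csv(out / "matrix.csv", index=False)
    manifest["stages"]["build"] = {
        "n_rows": len(matrix),
        "n_patients": int(matrix["patient_id"].nunique()),
        "rows_per_partition": matrix["partition"].value_counts().to_dict(),
    }

    # --- fit
    train = matrix[matrix["partition"] == "train"]
    fits: dict = {}
    fit_info: dict = {}
    for mc in config.model_classes:
        cc_train, dropped = complete_case_filter(train, mc)
        for oc in config.outcomes:
            label_col = OUTCOME_LABELS[oc]
            if cc_train[label_col].nunique() < 2:
                # a rare outcome can lack events at small cohort sizes;
                # record the cell as unfittable rather than abort the run
                fit_info[f"{mc}/{oc}"] = {"skipped": "single-class training labels"}
                continue
            try:
                fit = fit_discrete_logit(cc_train, mc, oc)
            except (SeparationError, SingularDesignError) as exc:
                fit_info[f"{mc}/{oc}"] = {"skipped": str(exc)}
                continue
            fits[(mc, oc)] = fit
            fit_info[f"{mc}/{oc}"] = {
                "n_rows": fit.n_rows,
                "n_events": fit.n_events,
                "converged": fit.converged,
                "dropped_fraction": round(dropped, 4),
            }
            (out / "models").mkdir(exist_ok=True)
            with open(out / "models" / f"{mc}__{oc}.json", "w") as fh:
                fh.write(fit.to_json())
    manifest["stages"]["fit"] = fit_info

    # --- evaluate
    strata = {
        str(name): grp
        for name, grp in matrix[matrix["partition"] != "train"].groupby("partition")
    }
    grid = evaluation_grid(
        fits, strata, B=config.bootstrap_B, seed=config.eval_seed, strict=False
    )
    grid.to_csv(out / "evaluation_grid.csv", index=False)
    grid_to_table(grid).to_csv(out / "evaluation_table.csv")
    if config.make_plots:
        eval_rows = matrix[matrix["partition"] == "validation"]
        plot_roc_panels(
            fits,
            eval_rows,
            outcomes=tuple(config.outcomes),
            path=str(out / "roc_panels.svg"),
        )
    manifest["stages"]["evaluate"] = {"n_cells": len(grid)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
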