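from __future__ import annotations

import numpy as np
import pytest

from akipredict import (
    SimConfig,
    apply_exclusions,
    build_matrix,
    detect_aki_table,
    generate_cohort,
    inject_missingness,
    split_cohort,
)


def make_fuzz_series(rng, min_len=2, max_len=50):
    """Random creatinine series: lengths 2-50, values 0.3-8.0 mg/dL,
    inter-measurement spacings 1-72 h."""
    n = int(rng.integers(min_len, max_len + 1))
    spacings = rng.uniform(1.0, 72.0, n - 1)
    times = np.concatenate([[0.0], np.cumsum(spacings)])
    values = rng.uniform(0.3, 8.0, n)
    return times, values


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_patients=400, seed=101)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    """Exclusion-filtered observation matrix with partition labels."""
    patients, measurements, exposures, truth = small_cohort
    measurements = inject_missingness(measurements, 0.08, seed=202)
    included, _ = apply_exclusions(patients, measurements)
    meas = measurements[measurements["patient_id"].isin(included["patient_id"])]
    exp = exposures[exposures["patient_id"].isin(included["patient_id"])]
    events = detect_aki_table(meas)
    matrix = build_matrix(included, meas, exp, events)
    part = split_cohort(included, seed=3)
    matrix = matrix.copy()
    matrix["partition"] = part.loc[matrix["patient_id"]].to_numpy()
    return included, matrix, events
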