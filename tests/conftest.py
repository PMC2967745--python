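import numpy as np
import pandas as pd
import pytest

from clinarray_ica import (
    IcaConfig,
    SyntheticConfig,
    build_clinarray,
    generate_records,
    knn_impute,
    standardize,
)


def records_from_rows(rows):
    """Build a record table from (patient, biomarker, value[, date]) tuples."""
    out = []
    for row in rows:
        patient, biomarker, value = row[:3]
        date = row[3] if len(row) > 3 else 0
        out.append(
            {"patient_id": patient, "biomarker": biomarker, "value": value,
             "visit_date": date}
        )
    return pd.DataFrame(out)


# Conditions of the planted-recovery benchmark: a 30-test panel driven by
# 3 latent factors, 3 factor-driven biomarkers at gain 5, idiosyncratic
# noise sd 4, full study-cohort scale.  The kurtosis contrast is used
# because the Laplace sources are strongly super-Gaussian (see
# docs/methods.md).
PLANTED_BENCHMARK = dict(
    n_patients=4000,
    n_biomarkers=30,
    n_sources=3,
    visits_per_patient=1,
    visit_noise_sd=0.0,
    observation_noise_sd=4.0,
    missing_rate=0.0,
    n_planted=3,
    planted_gain=5.0,
    planted_cross=0.4,
    seed=11,
)
BENCHMARK_ICA = dict(n_components=3, contrast="cube")
BENCHMARK_MASTER_SEED = 20260926


def standardized_planted_matrix(**overrides):
    """Generate the planted benchmark cohort and return the standardized
    clinarray plus its ground truth."""
    cfg = SyntheticConfig(**{**PLANTED_BENCHMARK, **overrides})
    records, truth = generate_records(cfg)
    matrix = build_clinarray(records)
    complete = knn_impute(matrix) if matrix.isna().any().any() else matrix
    standardized, _, _ = standardize(complete)
    return standardized, truth


@pytest.fixture(scope="session")
def planted_benchmark():
    return standardized_planted_matrix()


@pytest.fixture
def small_mixture():
    """A clean, well-separated 2-source Laplace mixture for ICA tests."""
    rng = np.random.default_rng(7)
    S = rng.laplace(0, 1 / np.sqrt(2), size=(2, 5000))
    S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    A = np.array([[2.0, 1.0], [1.0, 2.0]])
    return A @ S, A, S
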