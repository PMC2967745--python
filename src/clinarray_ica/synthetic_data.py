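"""Synthetic longitudinal lab-record generator with planted latent-factor structure.

The generator realizes the linear latent-factor model that the analysis
pipeline assumes: a biomarkers x patients matrix ``X = A @ S + noise`` in
which the rows of ``S`` are mutually independent, super-Gaussian (Laplace)
sources, and ``A`` is a random mixing matrix.  A configurable subset of
"planted" biomarkers receives strong, known loadings so that downstream
consensus extraction has a ground-truth answer to recover.  Each latent
cell value is then expanded into per-visit laboratory records with
measurement jitter, and a configurable fraction of patient-biomarker pairs
is never measured at all, exercising the pruning and imputation stages.

Planted biomarkers carry a dominant loading of magnitude ``planted_gain``
on a designated component and secondary cross-loadings of magnitude
``planted_cross * planted_gain`` on the remaining components (random signs,
fixed magnitudes).  The cross-loadings emulate the empirical behaviour of
factor-driven laboratory measurements, which correlate with every systemic
factor rather than exactly one; they are also what makes the planted set
recoverable by a mean-loading criterion, not only by a per-component
argmax criterion (see docs/methods.md for the analysis).
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_sources",
    "generate_mixing",
    "generate_records",
    "write_records",
    "write_ground_truth",
    "write_config",
    "read_config",
]

#: Laplace scale giving unit variance (var = 2 b^2).
_LAPLACE_UNIT_SCALE = 1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a simulated cohort.

    Defaults describe a pediatric-hospital-sized single-disease cohort:
    400 patients, a 30-test laboratory panel driven by 3 latent
    physiological factors, 3 strongly factor-driven biomarkers, ~5 visits
    per patient, and idiosyncratic (non-factor) variation four times the
    per-factor signal scale, i.e. biomarker communalities around 0.2.
    """

    n_patients: int = 400
    n_biomarkers: int = 30
    n_sources: int = 3
    visits_per_patient: int = 5
    visit_noise_sd: float = 0.5
    observation_noise_sd: float = 4.0
    missing_rate: float = 0.1
    n_planted: int = 3
    planted_gain: float = 5.0
    planted_cross: float = 0.4
    seed: int = 0
    prunable_safe: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_biomarkers < 1 or self.n_sources < 1:
            raise ValueError("n_patients, n_biomarkers and n_sources must be >= 1")
        if self.visits_per_patient < 1:
            raise ValueError("visits_per_patient must be >= 1")
        if self.n_sources > self.n_biomarkers:
            raise ValueError(
                f"n_sources ({self.n_sources}) must not exceed "
                f"n_biomarkers ({self.n_biomarkers})"
            )
        if self.n_planted > self.n_biomarkers:
            raise ValueError("n_planted must not exceed n_biomarkers")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.visit_noise_sd < 0 or self.observation_noise_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.planted_gain < 1.0:
            raise ValueError("planted_gain must be >= 1")
        if not (0.0 <= self.planted_cross <= 1.0):
            raise ValueError("planted_cross must lie in [0, 1]")
        if self.prunable_safe:
            # expected observed biomarkers per patient must clear the
            # downstream patient-pruning threshold (10)
            expected = self.n_biomarkers * (1.0 - self.missing_rate)
            if expected < 10:
                raise ValueError(
                    "prunable-safe config requires >= 10 expected observed "
                    f"biomarkers per patient, got {expected:.1f}"
                )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """True latent structure behind a generated cohort.

    ``sources`` is the k x n_patients matrix of independent factors,
    ``mixing`` the n_biomarkers x k loading matrix, and
    ``planted_biomarkers`` the identifiers of the factor-driven biomarkers
    the consensus stage is expected to recover.
    """

    sources: np.ndarray
    mixing: np.ndarray
    planted_biomarkers: frozenset
    patient_ids: list = field(default_factory=list)
    biomarker_ids: list = field(default_factory=list)

    @property
    def latent_matrix(self) -> np.ndarray:
        """Noise-free biomarkers x patients signal ``A @ S``."""
        return self.mixing @ self.sources


def generate_sources(k: int, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``k`` independent standardized Laplace sources of length ``n``.

    Each row is an i.i.d. standard-Laplace sample, then exactly centred to
    sample mean 0 and scaled to sample variance 1 (population convention).
    The Laplace law is super-Gaussian (excess kurtosis 3), which is what
    a negentropy-maximizing separation algorithm needs to identify the
    rotation.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    rng = np.random.default_rng(seed)
    S = rng.laplace(0.0, _LAPLACE_UNIT_SCALE, size=(k, n))
    S = S - S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1)
    sd[sd == 0] = 1.0  # degenerate only for n == 1
    return S / sd[:, None]


def generate_mixing(
    m: int,
    k: int,
    planted: set | frozenset | list = (),
    gain: float = 5.0,
    seed: int = 0,
    cross: float = 0.4,
) -> np.ndarray:
    """Random m x k mixing matrix with planted dominant biomarkers.

    Background entries are standard normal.  Each planted biomarker row
    (cycling through component columns) is overwritten with a loading of
    magnitude ``gain`` on its designated component and ``cross * gain`` on
    every other component, keeping the signs of the original draws.  The
    fixed magnitudes guarantee the planted rows dominate their columns:
    with gain 5 the probability that any background |N(0,1)| entry exceeds
    the primary loading is negligible.

    The matrix is regenerated with an incremented seed in the (measure-
    zero, but numerically possible) event of column-rank deficiency.
    """
    if k > m:
        raise ValueError(f"k ({k}) must not exceed m ({m})")
    planted = sorted(planted)
    if planted and (min(planted) < 0 or max(planted) >= m):
        raise ValueError("planted indices must lie in [0, m)")
    if gain < 1.0:
        raise ValueError("gain must be >= 1")
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        A = rng.standard_normal((m, k))
        for i, b in enumerate(planted):
            primary = i % k
            for c in range(k):
                magnitude = gain if c == primary else cross * gain
                A[b, c] = np.sign(A[b, c]) * magnitude if A[b, c] != 0 else magnitude
        if np.linalg.matrix_rank(A) == k:
            return A
    raise RuntimeError("could not generate a full-column-rank mixing matrix")


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds via the numpy seed-sequence tree."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) for s in state]


def generate_records(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort of longitudinal lab records.

    Returns a long-format record table (patient_id, biomarker, value,
    visit_date) plus the generating ground truth.  The latent cell value
    for biomarker b and patient p is ``(A @ S)[b, p]`` plus one draw of
    observation noise; each of the patient's visits then re-measures that
    cell with independent jitter of sd ``visit_noise_sd``.  Cells selected
    as missing (independently, with probability ``missing_rate``) emit no
    records at all.  Output is byte-identical for identical configs.
    """
    cfg = config
    m, n, k = cfg.n_biomarkers, cfg.n_patients, cfg.n_sources
    s_seed, a_seed, noise_seed, miss_seed, visit_seed = _derive_seeds(cfg.seed, 5)

    S = generate_sources(k, n, s_seed)
    planted_idx = list(range(cfg.n_planted))
    A = generate_mixing(m, k, planted_idx, cfg.planted_gain, a_seed, cfg.planted_cross)

    rng_noise = np.random.default_rng(noise_seed)
    X = A @ S + cfg.observation_noise_sd * rng_noise.standard_normal((m, n))

    rng_miss = np.random.default_rng(miss_seed)
    observed = rng_miss.random((m, n)) >= cfg.missing_rate

    v = cfg.visits_per_patient
    rng_visit = np.random.default_rng(visit_seed)
    jitter = cfg.visit_noise_sd * rng_visit.standard_normal((m, n, v))

    biomarker_ids = [f"bm{i + 1:03d}" for i in range(m)]
    patient_ids = [f"pt{j + 1:05d}" for j in range(n)]

    # patient-major record order; visit dates are weekly ordinal offsets
    b_idx, p_idx = np.nonzero(observed)
    order = np.lexsort((b_idx, p_idx))
    b_idx, p_idx = b_idx[order], p_idx[order]
    values = (X[b_idx, p_idx][:, None] + jitter[b_idx, p_idx, :]).ravel()
    records = pd.DataFrame(
        {
            "patient_id": np.repeat([patient_ids[j] for j in p_idx], v),
            "biomarker": np.repeat([biomarker_ids[i] for i in b_idx], v),
            "value": values,
            "visit_date": np.tile(np.arange(v) * 7, len(b_idx)),
        }
    )

    truth = GroundTruth(
        sources=S,
        mixing=A,
        planted_biomarkers=frozenset(biomarker_ids[i] for i in planted_idx),
        patient_ids=patient_ids,
        biomarker_ids=biomarker_ids,
    )
    return records, truth


# ---------------------------------------------------------------------------
# file I/O

def write_records(records: pd.DataFrame, path: str | pathlib.Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, directory: str | pathlib.Path) -> None:
    """Write sources, mixing and the planted list as delimited text."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    k = truth.sources.shape[0]
    comp_ids = [f"ic{c + 1}" for c in range(k)]
    pd.DataFrame(truth.sources, index=comp_ids, columns=truth.patient_ids).to_csv(
        directory / "true_sources.tsv", sep="\t"
    )
    pd.DataFrame(truth.mixing, index=truth.biomarker_ids, columns=comp_ids).to_csv(
        directory / "true_mixing.tsv", sep="\t"
    )
    (directory / "planted_biomarkers.txt").write_text(
        "\n".join(sorted(truth.planted_biomarkers)) + "\n"
    )


def write_config(config: SyntheticConfig, path: str | pathlib.Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path: str | pathlib.Path) -> SyntheticConfig:
    with open(path) as fh:
        return SyntheticConfig.from_dict(yaml.safe_load(fh))
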