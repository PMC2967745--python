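"""Missing-value imputation and per-biomarker standardization.

Missing clinarray cells are filled by K-nearest-neighbour imputation in
the style used for expression matrices: the neighbours of a biomarker row
are other biomarker rows, compared by root-mean-square difference over
co-observed patients, and a missing cell is the inverse-distance-weighted
mean of the K nearest rows observed at that patient.  After imputation
every biomarker row is centred to mean zero and scaled to unit variance
(population convention, matching the whitening step's covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ImputationConfig", "knn_impute", "standardize"]


@dataclass(frozen=True)
class ImputationConfig:
    """K = 10 follows standard KNN-imputation practice for omics matrices;
    ``min_shared_columns`` is the minimum number of co-observed patients
    for a row-to-row distance to be considered defined."""

    k_neighbors: int = 10
    min_shared_columns: int = 3

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.min_shared_columns < 1:
            raise ValueError("min_shared_columns must be >= 1")


def knn_impute(
    matrix: pd.DataFrame, config: ImputationConfig | None = None
) -> pd.DataFrame:
    """Fill every missing cell; observed cells are returned bit-for-bit.

    For a missing cell (b, p): candidate neighbours are the biomarker rows
    observed at patient p whose distance to row b is defined (at least
    ``min_shared_columns`` co-observed patients).  Distance is the RMS
    difference over co-observed patients, so sparsity does not inflate it.
    The imputed value is the 1/distance-weighted mean of the candidates'
    values at p, truncated to the K nearest; exact duplicates (distance 0)
    take precedence with a plain mean.  A cell with no candidates falls
    back to the row mean of b.
    """
    if config is None:
        config = ImputationConfig()
    X = matrix.to_numpy(dtype=float, copy=True)
    m, n = X.shape
    observed = np.isfinite(X)
    if not observed.any(axis=1).all():
        bad = matrix.index[~observed.any(axis=1)][0]
        raise ValueError(f"biomarker row {bad!r} has no observed values")
    col_has_obs = observed.any(axis=0)
    if not col_has_obs.all():
        bad = matrix.columns[int(np.argmax(~col_has_obs))]
        raise ValueError(f"patient column {bad!r} has no observed values")
    if observed.all():
        return matrix.copy()

    # pairwise RMS distances over co-observed columns
    Xz = np.where(observed, X, 0.0)
    obs_f = observed.astype(float)
    shared = obs_f @ obs_f.T                      # co-observed counts
    sq = Xz**2
    # sum over shared columns of (x_i - x_j)^2
    cross = Xz @ Xz.T
    sum_sq_i = sq @ obs_f.T
    d2 = sum_sq_i + sum_sq_i.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(d2, 0.0) / shared)
    dist[shared < config.min_shared_columns] = np.nan
    np.fill_diagonal(dist, np.nan)

    row_means = np.nanmean(np.where(observed, X, np.nan), axis=1)
    result = X.copy()
    K = config.k_neighbors
    for b, p in zip(*np.nonzero(~observed)):
        candidates = np.nonzero(observed[:, p] & np.isfinite(dist[b]))[0]
        if candidates.size == 0:
            result[b, p] = row_means[b]
            continue
        d = dist[b, candidates]
        if candidates.size > K:
            # K nearest; ties broken by row order via stable argsort
            nearest = np.argsort(d, kind="stable")[:K]
            candidates, d = candidates[nearest], d[nearest]
        zero = d == 0.0
        if zero.any():
            result[b, p] = X[candidates[zero], p].mean()
        else:
            w = 1.0 / d
            result[b, p] = np.average(X[candidates, p], weights=w)
    return pd.DataFrame(result, index=matrix.index, columns=matrix.columns)


def standardize(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Centre each biomarker row to mean 0 and scale to unit variance.

    Uses the population (divide-by-n) convention.  Returns the transformed
    matrix together with the per-row means and scales so the transform can
    be inverted exactly.  Raises on constant rows, naming the biomarker.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("standardize requires a complete (imputed) matrix")
    if X.shape[1] < 2:
        raise ValueError("standardize requires at least 2 patients")
    means = X.mean(axis=1)
    scales = X.std(axis=1)  # population convention
    zero = scales == 0.0
    if zero.any():
        bad = matrix.index[np.argmax(zero)]
        raise ValueError(f"biomarker {bad!r} has zero variance; cannot standardize")
    Z = (X - means[:, None]) / scales[:, None]
    return (
        pd.DataFrame(Z, index=matrix.index, columns=matrix.columns),
        pd.Series(means, index=matrix.index, name="mean"),
        pd.Series(scales, index=matrix.index, name="scale"),
    )
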