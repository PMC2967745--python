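"""Separation-quality metrics for blind source separation.

ICA recovers sources only up to permutation, sign and scale, so recovery
is scored after an optimal matching: estimated and reference sources are
paired by maximizing total absolute correlation (Hungarian assignment).
The Amari index summarizes how far ``unmixing @ true_mixing`` is from a
signed permutation matrix; 0 means perfect separation, and the
normalization puts a random matrix near 1.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["match_components", "matched_abs_correlations", "amari_index"]


def match_components(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal pairing of estimated to reference source rows.

    Returns ``(perm, abs_corr)`` where ``perm[i]`` is the reference row
    matched to estimated row i and ``abs_corr[i]`` the absolute Pearson
    correlation of the pair.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape[1] != ref.shape[1]:
        raise ValueError("estimated and reference must have equal sample counts")
    corr = np.abs(_row_correlations(est, ref))
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm, corr[rows, cols]


def matched_abs_correlations(estimated: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Absolute correlations of optimally matched source pairs."""
    _, ac = match_components(estimated, reference)
    return ac


def amari_index(P: np.ndarray) -> float:
    """Normalized Amari separation error of a k x k system matrix.

    ``P = unmixing @ true_mixing`` for a perfect separation is a signed,
    scaled permutation, for which the index is exactly 0.  The index
    averages, over rows and columns, how much mass lies outside each
    line's dominant entry, normalized to [0, 1].
    """
    P = np.abs(np.asarray(P, dtype=float))
    k = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("Amari index requires a square matrix")
    if k == 1:
        return 0.0
    row_term = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col_term = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row_term + col_term) / (2.0 * k * (k - 1)))


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    a_norm = np.linalg.norm(a, axis=1, keepdims=True)
    b_norm = np.linalg.norm(b, axis=1, keepdims=True)
    a_norm[a_norm == 0] = 1.0
    b_norm[b_norm == 0] = 1.0
    return (a / a_norm) @ (b / b_norm).T
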