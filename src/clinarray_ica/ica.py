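"""FastICA decomposition of a standardized clinarray.

The model is ``X = A S``: each patient's standardized biomarker vector is
a linear mixture of statistically independent latent physiological
factors.  The decomposition estimates an unmixing matrix ``W`` with
``Y = W X`` approximating ``S`` (up to permutation, sign and scale — the
intrinsic indeterminacies of ICA), via the fixed-point FastICA iteration
on whitened data, using a negentropy-approximation contrast (tanh for the
logcosh contrast, u^3 for the kurtosis contrast).

The number of components can be set explicitly or estimated from the
eigenvalue scree of the sample covariance ("auto"): the retained count is
placed at the elbow, located by the maximum second difference
(acceleration) of the descending eigenvalue curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IcaConfig",
    "IcaRun",
    "whiten",
    "estimate_n_components",
    "fastica",
    "decompose",
]

#: relative eigenvalue cutoff below which a direction counts as rank-deficient
_RANK_RTOL = 1e-12
#: maximum allowed deviation of a "whitened" covariance from identity
_WHITE_ATOL = 1e-4


@dataclass(frozen=True)
class IcaConfig:
    """Settings of a single FastICA run.

    ``n_components`` may be a positive integer or ``"auto"`` (scree
    estimate).  ``contrast`` selects the negentropy approximation:
    ``"logcosh"`` (tanh nonlinearity; robust default) or ``"cube"``
    (kurtosis; faster fixed points for strongly super-Gaussian sources).
    """

    n_components: int | str = "auto"
    contrast: str = "logcosh"
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast not in ("logcosh", "cube"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_components != "auto":
            if not isinstance(self.n_components, (int, np.integer)) or self.n_components < 1:
                raise ValueError("n_components must be 'auto' or a positive integer")


@dataclass
class IcaRun:
    """Result of one decomposition.

    ``unmixing`` (k x m) maps standardized biomarker space to sources;
    ``mixing_est`` (m x k) is its pseudo-inverse, whose column c holds the
    biomarker loadings of component c; ``sources_est`` (k x n) has
    unit-variance rows.
    """

    unmixing: np.ndarray
    mixing_est: np.ndarray
    sources_est: np.ndarray
    seed: int
    converged: bool
    n_iter: int

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


class FastIcaResult(NamedTuple):
    rotation: np.ndarray
    converged: bool
    n_iter: int


def _cov_eig(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenpairs of the population sample covariance of rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    C = Xc @ Xc.T / X.shape[1]
    eigvals, eigvecs = np.linalg.eigh(C)
    return eigvals[::-1], eigvecs[:, ::-1]


def whiten(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the top-k principal directions and equalize variance.

    Returns ``(Z, whitening_map, eigenvalues)`` with
    ``Z = whitening_map @ X_centred`` having identity covariance
    (population convention).  Raises if ``k`` exceeds the numerical rank
    of the sample covariance.
    """
    X = np.asarray(X, dtype=float)
    eigvals, eigvecs = _cov_eig(X)
    if k > len(eigvals) or eigvals[k - 1] <= _RANK_RTOL * max(eigvals[0], 0.0):
        raise np.linalg.LinAlgError(
            f"requested {k} components but the data have numerical rank "
            f"{int((eigvals > _RANK_RTOL * eigvals[0]).sum())}"
        )
    ev_k = eigvals[:k]
    whitening_map = (1.0 / np.sqrt(ev_k))[:, None] * eigvecs[:, :k].T
    Xc = X - X.mean(axis=1, keepdims=True)
    return whitening_map @ Xc, whitening_map, ev_k


def estimate_n_components(eigenvalues: np.ndarray) -> int:
    """Scree elbow: component count from the eigenvalue curve's bend.

    The elbow is the interior index where the second difference
    (acceleration) of the descending eigenvalue curve is maximal — i.e.
    the first eigenvalue AFTER the last retained one — so the retained
    count is that index minus one.  The curve is taken on a log scale:
    eigenvalue decay is multiplicative, and on a linear scale a single
    dominant factor can out-accelerate the true signal/noise elbow.
    Ties resolve to the smallest count.  With fewer than 3 eigenvalues
    there is no interior point; all components are retained with a
    logged warning.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-9 * max(abs(ev[0]), 1.0)):
        raise ValueError("eigenvalues must be in descending order")
    if np.any(ev < -1e-9):
        raise ValueError("eigenvalues must be nonnegative")
    if len(ev) < 3:
        logger.warning(
            "scree estimate needs >= 3 eigenvalues, got %d; retaining all", len(ev)
        )
        return len(ev)
    floor = max(ev[0], 1.0) * 1e-15  # keep exact zeros (rank deficiency) loggable
    log_ev = np.log(np.maximum(ev, floor))
    accel = log_ev[:-2] - 2.0 * log_ev[1:-1] + log_ev[2:]  # accel[i] at eigenvalue i+1
    # round to kill floating-point noise so exact ties resolve to the smallest count
    elbow = int(np.argmax(np.round(accel, decimals=12))) + 1  # 0-based elbow position
    return max(elbow, 1)


def _symmetric_decorrelation(W: np.ndarray) -> np.ndarray:
    d, E = np.linalg.eigh(W @ W.T)
    return (E * (1.0 / np.sqrt(d))) @ E.T @ W


def fastica(Z: np.ndarray, config: IcaConfig) -> FastIcaResult:
    """Symmetric (parallel) fixed-point FastICA on whitened data.

    All rows are updated together via
    ``w_i <- E[z g(w_i' z)] - E[g'(w_i' z)] w_i`` followed by symmetric
    decorrelation, so no estimation order is privileged (the consensus
    stage compares whole components across runs).  Convergence is reached
    when every row's direction change, measured sign-invariantly as
    ``|1 - |<w_new, w_old>||``, falls below ``tol``.  Non-convergence is
    reported in the result, not raised.
    """
    Z = np.asarray(Z, dtype=float)
    k, n = Z.shape
    C = Z @ Z.T / n
    if np.abs(C - np.eye(k)).max() > _WHITE_ATOL:
        raise ValueError("fastica requires whitened input (covariance must be identity)")

    rng = np.random.default_rng(config.seed)
    W = _symmetric_decorrelation(rng.standard_normal((k, k)))
    total_iter = 0
    # When a component is only weakly non-Gaussian the plain fixed-point
    # iteration can settle into a period-2 cycle around its fixed point.
    # The standard stabilization damps the update (the fixed points are
    # unchanged, but averaging successive iterates breaks the cycle), so
    # after a fruitless plain phase we retry with step 1/2, then 1/4.
    for step in (1.0, 0.5, 0.25):
        for _ in range(config.max_iter):
            total_iter += 1
            WZ = W @ Z
            if config.contrast == "logcosh":
                G = np.tanh(WZ)
                g_prime_mean = (1.0 - G**2).mean(axis=1)
            else:  # cube
                G = WZ**3
                g_prime_mean = 3.0 * (WZ**2).mean(axis=1)
            target = _symmetric_decorrelation(G @ Z.T / n - g_prime_mean[:, None] * W)
            if step < 1.0:
                # keep the signs aligned so the average does not cancel
                target = target * np.sign(np.sum(target * W, axis=1))[:, None]
                W_new = _symmetric_decorrelation((1.0 - step) * W + step * target)
            else:
                W_new = target
            delta = np.max(np.abs(1.0 - np.abs(np.sum(W_new * W, axis=1))))
            W = W_new
            if delta < config.tol:
                return FastIcaResult(W, True, total_iter)
    return FastIcaResult(W, False, total_iter)


def decompose(X: np.ndarray | pd.DataFrame, config: IcaConfig) -> IcaRun:
    """Whiten, (optionally) pick k by scree, run FastICA, assemble the run.

    ``X`` must be a standardized complete matrix (biomarker rows).  The
    returned run satisfies ``sources_est = unmixing @ X`` with
    unit-variance source rows, and ``mixing_est = pinv(unmixing)`` so that
    ``mixing_est @ sources_est`` is the rank-k reconstruction of ``X``.
    """
    X = np.asarray(X, dtype=float)
    if config.n_components == "auto":
        eigvals, _ = _cov_eig(X)
        k = estimate_n_components(np.maximum(eigvals, 0.0))
    else:
        k = int(config.n_components)
        if k > min(X.shape):
            raise ValueError(f"n_components ({k}) exceeds min(m, n) = {min(X.shape)}")
    Z, whitening_map, _ = whiten(X, k)
    rotation, converged, n_iter = fastica(Z, config)
    unmixing = rotation @ whitening_map
    sources = unmixing @ X
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    unmixing = unmixing / sd[:, None]
    sources = sources / sd[:, None]
    mixing_est = np.linalg.pinv(unmixing)
    return IcaRun(
        unmixing=unmixing,
        mixing_est=mixing_est,
        sources_est=sources,
        seed=config.seed,
        converged=converged,
        n_iter=n_iter,
    )
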