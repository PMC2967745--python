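"""Ensemble ICA and consensus extraction of significant biomarkers.

FastICA converges to local optima that depend on its random
initialization, and components come out in no particular order, so a
single run is not a reliable basis for calling biomarkers significant.
The pipeline therefore repeats the decomposition (500 runs by default)
from independent random starts and extracts significant biomarkers from
the collection of absolute loading scores by two rules:

1. *top-fraction*: biomarkers whose mean absolute loading (across
   components and runs) reaches the top ``fraction`` of a reference
   distribution — either the pooled distribution of all individual
   absolute loadings (``threshold_basis="pooled"``) or the distribution
   of the per-biomarker means themselves (``threshold_basis="means"``);
2. *argmax-consistency*: biomarkers that carry the highest absolute
   loading of at least one component in every converged run.

Both rules are permutation- and sign-invariant by construction, so no
cross-run component alignment is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ica import IcaConfig, decompose

logger = logging.getLogger(__name__)

__all__ = [
    "LoadingEnsemble",
    "ConsensusResult",
    "run_ensemble",
    "significant_by_top_fraction",
    "significant_by_argmax_consistency",
    "extract_significant",
    "summarize",
]


@dataclass
class LoadingEnsemble:
    """Absolute loading scores collected across an ICA ensemble.

    ``abs_loadings`` has shape (n_runs, m biomarkers, k components);
    entry (r, b, c) is ``|mixing_est[b, c]|`` of run r.
    """

    abs_loadings: np.ndarray
    biomarker_ids: list
    run_seeds: list
    convergence_flags: np.ndarray
    n_iters: list = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return self.abs_loadings.shape[0]

    @property
    def n_converged(self) -> int:
        return int(self.convergence_flags.sum())

    @property
    def converged_loadings(self) -> np.ndarray:
        return self.abs_loadings[self.convergence_flags]


@dataclass
class ConsensusResult:
    significant_topfrac: list
    significant_argmax: list
    mean_abs_loading: pd.Series
    threshold_value: float
    argmax_counts: pd.Series
    methods_agree: bool


def _derive_run_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Distinct, reproducible per-run seeds from a splittable scheme."""
    children = np.random.SeedSequence(master_seed).spawn(n_runs)
    seeds = [int(c.generate_state(1, dtype=np.uint32)[0]) for c in children]
    seen: dict[int, int] = {}
    for i, s in enumerate(seeds):  # collisions are ~2^-32 but must not happen
        while s in seen:
            s = (s + 1) % 2**32
        seen[s] = i
        seeds[i] = s
    return seeds


def run_ensemble(
    X: pd.DataFrame | np.ndarray,
    base_config: IcaConfig | None = None,
    n_runs: int = 500,
    master_seed: int = 0,
) -> LoadingEnsemble:
    """Repeat the decomposition from ``n_runs`` independent random starts.

    The component count is fixed before the ensemble: if the base config
    says "auto" it is estimated once from the eigenvalue scree, so every
    run's components are comparable.  Runs that fail to converge are kept
    in the record but flagged, and excluded from all consensus statistics.
    Raises if more than half the runs fail to converge.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_config is None:
        base_config = IcaConfig()
    if isinstance(X, pd.DataFrame):
        biomarker_ids = list(X.index)
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        biomarker_ids = [f"bm{i + 1:03d}" for i in range(X_arr.shape[0])]

    if base_config.n_components == "auto":
        from .ica import _cov_eig, estimate_n_components

        eigvals, _ = _cov_eig(X_arr)
        k = estimate_n_components(np.maximum(eigvals, 0.0))
        logger.info("scree estimate: retaining %d components for the ensemble", k)
    else:
        k = int(base_config.n_components)

    seeds = _derive_run_seeds(master_seed, n_runs)
    loadings = np.empty((n_runs, X_arr.shape[0], k))
    flags = np.zeros(n_runs, dtype=bool)
    n_iters = []
    for r, seed in enumerate(seeds):
        cfg = IcaConfig(
            n_components=k,
            contrast=base_config.contrast,
            tol=base_config.tol,
            max_iter=base_config.max_iter,
            seed=seed,
        )
        run = decompose(X_arr, cfg)
        loadings[r] = np.abs(run.mixing_est)
        flags[r] = run.converged
        n_iters.append(run.n_iter)

    n_bad = n_runs - int(flags.sum())
    if n_bad:
        logger.warning("%d of %d ensemble runs did not converge", n_bad, n_runs)
    if n_bad > n_runs / 2:
        raise RuntimeError(
            f"ensemble quality failure: {n_bad}/{n_runs} runs did not converge"
        )
    return LoadingEnsemble(
        abs_loadings=loadings,
        biomarker_ids=biomarker_ids,
        run_seeds=seeds,
        convergence_flags=flags,
        n_iters=n_iters,
    )


def significant_by_top_fraction(
    ensemble: LoadingEnsemble,
    fraction: float = 0.01,
    threshold_basis: str = "pooled",
) -> tuple[list, float, pd.Series]:
    """Mean-loading rule: biomarkers whose mean |loading| is in the top
    ``fraction`` of the reference distribution.

    With ``threshold_basis="pooled"`` the threshold is the
    ``1 - fraction`` quantile (linear interpolation) of every individual
    absolute loading across biomarkers, components and converged runs;
    with ``"means"`` it is that quantile of the per-biomarker means.
    Selection uses ``>=``, so a degenerate all-equal ensemble selects all
    biomarkers.  Returns (selected ids, threshold, per-biomarker means),
    selected sorted by descending mean.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if threshold_basis not in ("pooled", "means"):
        raise ValueError(f"unknown threshold_basis {threshold_basis!r}")
    L = ensemble.converged_loadings
    if L.size == 0:
        raise ValueError("ensemble has no converged runs")
    # component order within a run is arbitrary; sorting before reduction
    # makes the floating-point sums bit-exact under component permutation
    L = np.sort(L, axis=2)
    means = pd.Series(
        L.mean(axis=(0, 2)), index=ensemble.biomarker_ids, name="mean_abs_loading"
    )
    if threshold_basis == "pooled":
        threshold = float(np.quantile(L.ravel(), 1.0 - fraction))
    else:
        threshold = float(np.quantile(means.to_numpy(), 1.0 - fraction))
    selected = means[means >= threshold].sort_values(ascending=False)
    return list(selected.index), threshold, means


def significant_by_argmax_consistency(
    ensemble: LoadingEnsemble,
) -> tuple[list, pd.Series]:
    """Argmax rule: biomarkers loading highest on a component in ALL runs.

    For every converged run and component, the biomarker with the largest
    absolute loading of that component is recorded (exact ties broken by
    biomarker row order, and logged).  A biomarker is significant iff it
    wins at least one component in every converged run — strict
    universality, so 499 out of 500 runs is not enough.  Returns the
    selected ids (sorted by descending total win count) and the
    per-biomarker count of runs won.
    """
    L = ensemble.converged_loadings
    if L.size == 0:
        raise ValueError("ensemble has no converged runs")
    n_conv, m, k = L.shape
    winners = L.argmax(axis=1)  # (n_conv, k); argmax breaks ties by row order
    ties = (L == L.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.warning(
            "%d component argmax ties broken by biomarker order", int(ties.sum())
        )
    run_counts = np.zeros(m, dtype=int)   # runs in which b wins >= 1 component
    event_counts = np.zeros(m, dtype=int)  # total (run, component) wins
    for r in range(n_conv):
        row = winners[r]
        event_counts += np.bincount(row, minlength=m)
        run_counts += np.bincount(np.unique(row), minlength=m)
    counts = pd.Series(run_counts, index=ensemble.biomarker_ids, name="argmax_runs")
    universal = np.nonzero(run_counts == n_conv)[0]
    order = universal[np.argsort(-event_counts[universal], kind="stable")]
    return [ensemble.biomarker_ids[i] for i in order], counts


def extract_significant(
    ensemble: LoadingEnsemble,
    fraction: float = 0.01,
    threshold_basis: str = "pooled",
) -> ConsensusResult:
    """Run both extraction rules and check their agreement."""
    top_ids, threshold, means = significant_by_top_fraction(
        ensemble, fraction, threshold_basis
    )
    argmax_ids, counts = significant_by_argmax_consistency(ensemble)
    return ConsensusResult(
        significant_topfrac=top_ids,
        significant_argmax=argmax_ids,
        mean_abs_loading=means,
        threshold_value=threshold,
        argmax_counts=counts,
        methods_agree=set(top_ids) == set(argmax_ids),
    )


def summarize(ensemble: LoadingEnsemble, result: ConsensusResult) -> str:
    """Human-readable consensus report."""
    lines = [
        "consensus report",
        "================",
        f"runs: {ensemble.n_runs} total, {ensemble.n_converged} converged "
        f"({ensemble.n_runs - ensemble.n_converged} excluded)",
        f"components per run: {ensemble.abs_loadings.shape[2]}",
        f"loading threshold: {result.threshold_value:.6g}",
        "",
        "significant biomarkers (top-fraction rule):",
    ]
    if result.significant_topfrac:
        for b in result.significant_topfrac:
            lines.append(f"  {b}  mean |loading| = {result.mean_abs_loading[b]:.4f}")
    else:
        lines.append("  none significant")
    lines += ["", "significant biomarkers (argmax-consistency rule):"]
    if result.significant_argmax:
        for b in result.significant_argmax:
            lines.append(
                f"  {b}  argmax in {result.argmax_counts[b]}/{ensemble.n_converged} runs"
            )
    else:
        lines.append("  none significant")
    lines.append("")
    if result.methods_agree:
        lines.append("both extraction rules yielded exactly the same biomarker set")
    else:
        sym_diff = sorted(
            set(result.significant_topfrac) ^ set(result.significant_argmax)
        )
        lines.append(f"RULES DISAGREE; symmetric difference: {', '.join(sym_diff)}")
    return "\n".join(lines)
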