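"""Ensemble bookkeeping and the two consensus significance rules."""

import numpy as np
import pandas as pd
import pytest

from clinarray_ica import (
    IcaConfig,
    decompose,
    extract_significant,
    run_ensemble,
    significant_by_argmax_consistency,
    significant_by_top_fraction,
    summarize,
)
from clinarray_ica.consensus import LoadingEnsemble, _derive_run_seeds

from conftest import BENCHMARK_ICA, standardized_planted_matrix


def make_ensemble(loadings, flags=None, ids=None):
    loadings = np.asarray(loadings, dtype=float)
    R, m, _ = loadings.shape
    if flags is None:
        flags = np.ones(R, dtype=bool)
    if ids is None:
        ids = [f"b{i + 1}" for i in range(m)]
    return LoadingEnsemble(
        abs_loadings=np.abs(loadings),
        biomarker_ids=ids,
        run_seeds=list(range(R)),
        convergence_flags=np.asarray(flags, dtype=bool),
    )


@pytest.fixture(scope="module")
def planted_small():
    """Planted benchmark at reduced patient count, for cheap ensembles."""
    return standardized_planted_matrix(n_patients=1500)


class TestRunEnsemble:
    def test_single_run_equals_decompose(self, planted_small):
        X, _ = planted_small
        ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=1, master_seed=5)
        run = decompose(X.to_numpy(), IcaConfig(**BENCHMARK_ICA, seed=ens.run_seeds[0]))
        assert np.array_equal(ens.abs_loadings[0], np.abs(run.mixing_est))

    def test_deterministic_given_master_seed(self, planted_small):
        X, _ = planted_small
        e1 = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=3, master_seed=7)
        e2 = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=3, master_seed=7)
        assert e1.run_seeds == e2.run_seeds
        assert np.array_equal(e1.abs_loadings, e2.abs_loadings)

    def test_components_stable_across_runs(self, planted_small):
        # well-separated mixture: every run's components must match run 0's
        # after permutation/sign alignment
        X, _ = planted_small
        ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=10, master_seed=1)
        ref = ens.abs_loadings[0]
        for r in range(1, 10):
            cur = ens.abs_loadings[r]
            corr = np.abs(np.corrcoef(ref.T, cur.T)[:3, 3:])
            # greedy row-max: each ref component has a near-identical partner
            assert corr.max(axis=1).min() > 0.95

    def test_run_seeds_distinct(self):
        seeds = _derive_run_seeds(0, 2000)
        assert len(set(seeds)) == 2000

    def test_majority_nonconvergence_raises(self, monkeypatch, planted_small):
        X, _ = planted_small
        import clinarray_ica.consensus as cons

        real = cons.decompose

        def broken(X_arr, cfg):
            run = real(X_arr, cfg)
            run.converged = False
            return run

        monkeypatch.setattr(cons, "decompose", broken)
        with pytest.raises(RuntimeError, match="ensemble quality"):
            run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=4, master_seed=2)


class TestTopFractionRule:
    def test_pooled_percentile_selects_outlier(self):
        # one run, one component, 100 biomarkers: loading 10 vs 99 ones;
        # the pooled 99th percentile (~1.09) isolates the outlier
        loadings = np.ones((1, 100, 1))
        loadings[0, 41, 0] = 10.0
        ids, threshold, means = significant_by_top_fraction(
            make_ensemble(loadings), fraction=0.01, threshold_basis="pooled"
        )
        assert ids == ["b42"]
        assert 1.0 < threshold < 10.0

    def test_all_equal_loadings_select_everything(self):
        ids, threshold, _ = significant_by_top_fraction(
            make_ensemble(np.full((3, 5, 2), 2.0)), fraction=0.01
        )
        assert len(ids) == 5
        assert threshold == pytest.approx(2.0)

    def test_nonconverged_runs_excluded(self):
        loadings = np.ones((2, 4, 1))
        loadings[1, 0, 0] = 50.0  # only in the non-converged run
        ens = make_ensemble(loadings, flags=[True, False])
        ids, _, means = significant_by_top_fraction(ens, fraction=0.2)
        assert means["b1"] == pytest.approx(1.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            significant_by_top_fraction(make_ensemble(np.ones((1, 3, 1))), fraction=1.5)


class TestArgmaxRule:
    def test_single_run_winners(self):
        loadings = np.ones((1, 8, 2)) * 0.1
        loadings[0, 2, 0] = 5.0  # b3 wins component 1
        loadings[0, 6, 1] = 4.0  # b7 wins component 2
        ids, counts = significant_by_argmax_consistency(make_ensemble(loadings))
        assert set(ids) == {"b3", "b7"}
        assert counts["b3"] == 1 and counts["b7"] == 1

    def test_one_missed_run_disqualifies(self):
        # strict universality: winning 499 of 500 runs is not enough
        R = 20
        loadings = np.ones((R, 5, 1)) * 0.1
        loadings[:, 1, 0] = 5.0
        loadings[R - 1, 1, 0] = 0.0
        loadings[R - 1, 3, 0] = 6.0
        ids, counts = significant_by_argmax_consistency(make_ensemble(loadings))
        assert "b2" not in ids
        assert counts["b2"] == R - 1

    def test_win_events_conserved(self, planted_small):
        X, _ = planted_small
        ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=8, master_seed=3)
        L = ens.converged_loadings
        winners = L.argmax(axis=1)
        total_events = sum(
            np.bincount(winners[r], minlength=L.shape[1]).sum()
            for r in range(L.shape[0])
        )
        assert total_events == L.shape[0] * L.shape[2]

    def test_tie_broken_by_row_order(self):
        loadings = np.zeros((1, 4, 1))
        loadings[0, 1, 0] = 3.0
        loadings[0, 2, 0] = 3.0
        ids, _ = significant_by_argmax_consistency(make_ensemble(loadings))
        assert ids == ["b2"]


class TestConsensusInvariances:
    def test_permutation_and_sign_invariance_exact(self, planted_small):
        X, _ = planted_small
        ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=6, master_seed=4)
        res = extract_significant(ens, fraction=0.1, threshold_basis="means")

        rng = np.random.default_rng(0)
        scrambled = ens.abs_loadings.copy()
        for r in range(scrambled.shape[0]):
            perm = rng.permutation(scrambled.shape[2])
            signs = rng.choice([-1.0, 1.0], size=scrambled.shape[2])
            scrambled[r] = np.abs(scrambled[r][:, perm] * signs)
        ens2 = LoadingEnsemble(
            abs_loadings=scrambled,
            biomarker_ids=ens.biomarker_ids,
            run_seeds=ens.run_seeds,
            convergence_flags=ens.convergence_flags,
        )
        res2 = extract_significant(ens2, fraction=0.1, threshold_basis="means")
        assert res.significant_topfrac == res2.significant_topfrac
        assert res.significant_argmax == res2.significant_argmax
        assert res.threshold_value == res2.threshold_value
        pd.testing.assert_series_equal(res.argmax_counts, res2.argmax_counts)

    def test_planted_gain_monotonicity(self):
        # raising the planted gain never evicts a planted biomarker from
        # either significant set (fixed seeds, gains 3 < 5 < 8)
        in_top, in_arg = [], []
        for gain in (3.0, 5.0, 8.0):
            X, truth = standardized_planted_matrix(
                n_patients=1500, planted_gain=gain
            )
            ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=8, master_seed=6)
            res = extract_significant(ens, fraction=0.1, threshold_basis="means")
            planted = truth.planted_biomarkers
            in_top.append(planted & set(res.significant_topfrac))
            in_arg.append(planted & set(res.significant_argmax))
        assert in_top[0] <= in_top[1] <= in_top[2]
        assert in_arg[0] <= in_arg[1] <= in_arg[2]


class TestSummarize:
    def test_report_renders_empty_and_disagreement(self):
        loadings = np.ones((1, 3, 1))
        loadings[0, 0, 0] = 9.0
        ens = make_ensemble(loadings)
        res = extract_significant(ens, fraction=0.5, threshold_basis="pooled")
        report = summarize(ens, res)
        if res.methods_agree:
            assert "same biomarker set" in report
        else:
            assert "DISAGREE" in report

    def test_report_lists_planted(self, planted_small):
        X, truth = planted_small
        ens = run_ensemble(X, IcaConfig(**BENCHMARK_ICA), n_runs=10, master_seed=8)
        res = extract_significant(ens, fraction=0.1, threshold_basis="means")
        report = summarize(ens, res)
        for b in truth.planted_biomarkers:
            assert b in report
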