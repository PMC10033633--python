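"""PCA, SPA and GA reduction: oracles and invariants."""

import itertools

import numpy as np
import pytest

from fibropsi.reduce import (
    CostSpec,
    ga_select,
    pca_fit,
    pca_transform,
    run_triplicate_ga,
    spa_select,
    subset_cost,
)


def _planted_problem(n=40, p=8, sep_col=3, gap=6.0, seed=0):
    """Gaussian noise matrix with one perfectly separating column."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, p))
    y = np.asarray(["CG"] * (n // 2) + ["FG"] * (n // 2), dtype=object)
    X[n // 2:, sep_col] += gap
    return X, y


class TestPca:
    def test_collinear_data_has_unit_pc1(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        res = pca_fit(X, n_pc=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        res = pca_fit(X, n_pc=6)
        recon = res.scores_train @ res.loadings.T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)

    def test_loadings_orthonormal_and_evr_sorted(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 12))
        res = pca_fit(X, n_pc=5)
        np.testing.assert_allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1.0 + 1e-12

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 9))
        res = pca_fit(X, n_pc=4)
        sk = sklearn.PCA(n_components=4).fit(X)
        np.testing.assert_allclose(
            np.abs(res.loadings), np.abs(sk.components_.T), atol=1e-8
        )
        np.testing.assert_allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-8
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="no variance"):
            pca_fit(np.ones((5, 3)), n_pc=1)

    def test_projection_uses_training_statistics_only(self):
        rng = np.random.default_rng(5)
        Xtr = rng.normal(size=(20, 6))
        Xte = rng.normal(size=(8, 6))
        res = pca_fit(Xtr, n_pc=3)
        before = pca_transform(res, Xte)
        # refit after scrambling the test rows: the fit cannot change
        res2 = pca_fit(Xtr, n_pc=3)
        after = pca_transform(res2, Xte[::-1])[::-1]
        np.testing.assert_allclose(before, after)


class TestSubsetCost:
    def test_perfect_separator_has_zero_cost(self):
        X, y = _planted_problem()
        assert subset_cost(X, y, [3]) == 0.0

    def test_noise_column_near_chance(self):
        X, y = _planted_problem()
        assert subset_cost(X, y, [0]) > 0.25


class TestSpa:
    def test_finds_single_perfect_separator(self):
        X, y = _planted_problem(sep_col=5)
        mz = np.arange(100, 108)  # column 5 -> label 105
        res = spa_select(X, y, mz_labels=mz, max_vars=4)
        assert res.cost == 0.0
        assert res.selected_mz == [105]

    def test_duplicate_column_never_in_same_chain(self):
        X, y = _planted_problem(p=6)
        X[:, 4] = X[:, 2]  # exact duplicate
        res = spa_select(X, y, max_vars=6)
        for chain in res.diagnostics["chains"].values():
            assert not ({2, 4} <= set(chain))

    def test_cost_never_better_than_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        spec = CostSpec()
        for trial in range(5):
            X = rng.normal(size=(24, 6))
            y = np.asarray(["CG"] * 12 + ["FG"] * 12, dtype=object)
            X[12:, rng.integers(0, 6)] += rng.uniform(1.0, 3.0)
            res = spa_select(X, y, max_vars=4)
            oracle = min(
                subset_cost(X, y, list(cols), spec)
                for k in range(1, 5)
                for cols in itertools.combinations(range(6), k)
            )
            assert res.cost >= oracle - 1e-12

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.asarray(["CG"] * 10, dtype=object)
        with pytest.raises(ValueError, match="both classes"):
            spa_select(X, y)


class TestGa:
    def test_trace_is_non_increasing(self):
        X, y = _planted_problem(n=30, p=12)
        res = ga_select(X, y, generations=10, pop_size=10, seed=2)
        trace = res.diagnostics["trace_best"]
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_seeded_determinism(self):
        X, y = _planted_problem(n=30, p=12)
        a = ga_select(X, y, seed=5)
        b = ga_select(X, y, seed=5)
        assert a.selected_mz == b.selected_mz
        assert a.diagnostics["trace_best"] == b.diagnostics["trace_best"]

    def test_zero_mutation_identical_population_is_static(self):
        X, y = _planted_problem(n=20, p=6)
        mask = np.zeros((8, 6), dtype=bool)
        mask[:, 1] = True  # every individual identical
        res = ga_select(
            X, y, pop_size=8, generations=5, seed=0,
            mutation_rate=0.0, initial_population=mask,
        )
        trace = res.diagnostics["trace_best"]
        assert len(set(trace)) == 1
        assert res.selected_idx == [1]

    def test_cap_respected_on_signal_free_data(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(30, 40))
        y = np.asarray(["CG"] * 15 + ["FG"] * 15, dtype=object)
        for seed in (1, 2, 3):
            res = ga_select(X, y, max_vars=10, seed=seed)
            assert len(res.selected_mz) <= 10
            assert len(set(res.selected_mz)) == len(res.selected_mz)

    def test_planted_pair_recovered_by_majority_of_seeds(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(40, 20))
        y = np.asarray(["CG"] * 20 + ["FG"] * 20, dtype=object)
        X[20:, 5] += 2.5   # m/z label 305
        X[20:, 19] += 3.0  # m/z label 319
        mz = np.arange(300, 320)
        hits = sum(
            bool({305, 319} & set(ga_select(X, y, mz_labels=mz, seed=s).selected_mz))
            for s in (1, 2, 3)
        )
        assert hits >= 2


class TestTriplicateGa:
    def test_same_seed_three_times_is_identical(self):
        X, y = _planted_problem(n=24, p=8)
        runs = run_triplicate_ga(X, y, seeds=(7, 7, 7))
        assert runs[0].selected_mz == runs[1].selected_mz == runs[2].selected_mz

    def test_requires_three_seeds(self):
        X, y = _planted_problem(n=24, p=8)
        with pytest.raises(ValueError, match="three seeds"):
            run_triplicate_ga(X, y, seeds=(1, 2))

    def test_union_recovers_planted_variable(self):
        X, y = _planted_problem(n=40, p=10, sep_col=4, gap=5.0, seed=3)
        runs = run_triplicate_ga(X, y, seeds=(1, 2, 3))
        union = set().union(*(r.selected_mz for r in runs))
        assert 4 in union
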