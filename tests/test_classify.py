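"""LDA/QDA Mahalanobis discriminants, SVM, metrics and the model grid."""

import numpy as np
import pytest

from fibropsi.classify import (
    GRID_ORDER,
    GridConfig,
    PolyKernel,
    decision_scores,
    evaluate,
    lda_fit,
    predict,
    qda_fit,
    run_grid,
    svm_fit,
)
from fibropsi.io import SpectralMatrix
from fibropsi.partition import kennard_stone


def _boundary_1d(model, lo, hi, n=200_001):
    """Numerically locate sign changes of the class-score difference."""
    xs = np.linspace(lo, hi, n)
    diff = decision_scores(model, xs[:, None])[:, 0] - decision_scores(model, xs[:, None])[:, 1]
    sign = np.sign(diff)
    idx = np.flatnonzero(np.diff(sign) != 0)
    roots = []
    for i in idx:
        a, b = xs[i], xs[i + 1]
        for _ in range(80):  # bisection
            m = 0.5 * (a + b)
            dm = (
                decision_scores(model, [[m]])[0, 0]
                - decision_scores(model, [[m]])[0, 1]
            )
            da = (
                decision_scores(model, [[a]])[0, 0]
                - decision_scores(model, [[a]])[0, 1]
            )
            if np.sign(dm) == np.sign(da):
                a = m
            else:
                b = m
        roots.append(0.5 * (a + b))
    return roots


class TestLda:
    def test_query_at_class_mean_is_assigned_there(self, separable_1d):
        X, y = separable_1d
        model = lda_fit(X, y)
        preds = predict(model, model.means)
        assert preds.tolist() == model.classes

    def test_equal_variance_boundary_is_midpoint_of_means(self, separable_1d):
        X, y = separable_1d
        model = lda_fit(X, y, priors="equal")
        (root,) = _boundary_1d(model, -5, 12)
        m0 = X[y == "CG"].mean()
        m1 = X[y == "FG"].mean()
        assert root == pytest.approx((m0 + m1) / 2, abs=1e-6)

    def test_unequal_priors_shift_boundary_by_analytic_offset(self, separable_1d):
        X, y = separable_1d
        model = lda_fit(X, y, priors=[0.9, 0.1])
        (root,) = _boundary_1d(model, -5, 12)
        m0, m1 = X[y == "CG"].mean(), X[y == "FG"].mean()
        # pooled variance as the fit computes it (ridge is negligible here)
        s0 = ((X[y == "CG"] - m0) ** 2).sum()
        s1 = ((X[y == "FG"] - m1) ** 2).sum()
        var = float((s0 + s1) / (len(X) - 2))
        expected = (m0 + m1) / 2 + var * np.log(0.9 / 0.1) / (m1 - m0)
        assert root == pytest.approx(expected, abs=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = np.asarray(["CG"] * 20 + ["FG"] * 20, dtype=object)
        X[20:] += 2.0
        Q = rng.normal(size=(10, 3))
        shift = np.array([100.0, -50.0, 7.0])
        a = predict(lda_fit(X, y), Q)
        b = predict(lda_fit(X + shift, y), Q + shift)
        assert a.tolist() == b.tolist()

    def test_agrees_with_sklearn_on_separated_classes(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 4))
        y = np.asarray(["CG"] * 30 + ["FG"] * 30, dtype=object)
        X[30:] += 1.5
        Q = rng.normal(size=(40, 4)) + 0.75
        mine = predict(lda_fit(X, y, priors="empirical"), Q)
        ref = sk.LinearDiscriminantAnalysis().fit(X, y).predict(Q)
        assert (mine == ref).mean() >= 0.95

    def test_tiny_class_rejected(self):
        X = np.zeros((3, 2))
        y = np.asarray(["CG", "CG", "FG"], dtype=object)
        with pytest.raises(ValueError, match="fewer than"):
            lda_fit(X, y)


class TestQda:
    def test_equal_covariances_reduce_to_lda(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 3))
        # class 2 is a pure translation -> identical sample covariance
        X = np.vstack([base, base + [4.0, -2.0, 1.0]])
        y = np.asarray(["CG"] * 50 + ["FG"] * 50, dtype=object)
        Q = rng.normal(size=(1000, 3)) + [2.0, -1.0, 0.5]
        a = predict(lda_fit(X, y), Q)
        b = predict(qda_fit(X, y), Q)
        assert a.tolist() == b.tolist()

    def test_unequal_variance_boundaries_match_quadratic_roots(self):
        rng = np.random.default_rng(6)
        x0 = rng.normal(0.0, 1.0, 200)
        x1 = rng.normal(5.0, 2.0, 200)
        X = np.concatenate([x0, x1])[:, None]
        y = np.asarray(["CG"] * 200 + ["FG"] * 200, dtype=object)
        model = qda_fit(X, y, priors="equal")
        roots = _boundary_1d(model, -20, 25)
        # closed-form roots of Q_0(x) = Q_1(x) with the fitted moments
        m0, v0 = float(model.means[0, 0]), float(model.covs[0, 0, 0])
        m1, v1 = float(model.means[1, 0]), float(model.covs[1, 0, 0])
        a = 1 / v0 - 1 / v1
        b = -2 * (m0 / v0 - m1 / v1)
        c = m0**2 / v0 - m1**2 / v1 + np.log(v0) - np.log(v1)
        expected = sorted(np.roots([a, b, c]).real)
        assert len(roots) == 2
        np.testing.assert_allclose(sorted(roots), expected, atol=1e-6)

    def test_query_at_mean_with_smaller_determinant_wins(self):
        rng = np.random.default_rng(10)
        x0 = rng.normal(0.0, 0.5, 100)
        x1 = rng.normal(0.0, 5.0, 100)  # same mean, larger spread
        X = np.concatenate([x0, x1])[:, None]
        y = np.asarray(["CG"] * 100 + ["FG"] * 100, dtype=object)
        model = qda_fit(X, y)
        common_mean = [[float(model.means[0, 0])]]
        assert predict(model, common_mean)[0] == "CG"


class TestSvm:
    def test_linearly_separable_points(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 3.0], [3.0, 4.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model = svm_fit(X, y, kernel=PolyKernel(degree=1, gamma=1.0, coef0=0.0), C_box=10.0)
        margins = model.diagnostics["train_margins"]
        assert (margins >= 1 - 1e-4).all()

    def test_xor_with_degree_two_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        model = svm_fit(X, y, kernel=PolyKernel(degree=2, gamma=1.0, coef0=1.0), C_box=100.0)
        scores = decision_scores(model, X)
        assert (np.sign(scores) == y).all()

    def test_kernel_symmetry(self):
        rng = np.random.default_rng(0)
        k = PolyKernel(degree=3, gamma=0.5, coef0=2.0)
        A = rng.normal(size=(6, 4))
        K = k.matrix(A, A, 0.5)
        np.testing.assert_allclose(K, K.T)

    def test_dual_feasibility_on_random_separable_sets(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            n = 30
            X = rng.normal(size=(n, 3))
            y = np.asarray([-1.0] * (n // 2) + [1.0] * (n // 2))
            X[y > 0] += 4.0
            C = 1.0
            model = svm_fit(X, y, C_box=C)
            alpha = model.diagnostics["all_alphas"]
            ytr = model.diagnostics["train_y"]
            assert (alpha >= -1e-9).all() and (alpha <= C + 1e-9).all()
            assert abs(float(alpha @ ytr)) < 1e-6
            assert (model.alphas > 0).all()

    def test_agrees_with_sklearn_on_test_points(self):
        svm_mod = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(77)
        X = rng.normal(size=(60, 4))
        y = np.asarray(["CG"] * 30 + ["FG"] * 30, dtype=object)
        X[30:] += 3.0
        Q = rng.normal(size=(50, 4)) + 1.5
        kernel = PolyKernel(degree=2, gamma=0.25, coef0=1.0)
        mine = predict(svm_fit(X, y, kernel=kernel, C_box=1.0), Q)
        ref = svm_mod.SVC(kernel="poly", degree=2, gamma=0.25, coef0=1.0, C=1.0).fit(X, y)
        assert (mine == ref.predict(Q)).mean() >= 0.95


class TestEvaluate:
    @pytest.mark.parametrize(
        "tp, tn, fp, fn, sens, spec, ac",
        [
            (10, 0, 0, 0, 100.0, float("nan"), 100.0),
            (0, 3, 1, 0, float("nan"), 75.0, 75.0),
            (3, 4, 1, 2, 60.0, 80.0, 70.0),
        ],
    )
    def test_examples(self, tp, tn, fp, fn, sens, spec, ac):
        pred = ["FG"] * tp + ["CG"] * tn + ["FG"] * fp + ["CG"] * fn
        true = ["FG"] * tp + ["CG"] * tn + ["CG"] * fp + ["FG"] * fn
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts, s, p, a = evaluate(pred, true)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (tp, tn, fp, fn)
        for got, want in ((s, sens), (p, spec), (a, ac)):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_zero_denominator_warns(self):
        with pytest.warns(UserWarning, match="SPEC undefined"):
            evaluate(["FG", "FG"], ["FG", "FG"])

    def test_illegal_label_rejected(self):
        with pytest.raises(ValueError, match="labels outside"):
            evaluate(["XX"], ["FG"])

    def test_random_tables_match_direct_arithmetic(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            pred = ["FG"] * tp + ["CG"] * tn + ["FG"] * fp + ["CG"] * fn
            true = ["FG"] * tp + ["CG"] * tn + ["CG"] * fp + ["FG"] * fn
            counts, s, p, a = evaluate(pred, true)
            assert s == 100.0 * tp / (tp + fn)
            assert p == 100.0 * tn / (tn + fp)
            assert a == 100.0 * (tp + tn) / (tp + tn + fp + fn)


class TestRunGrid:
    def test_emits_exactly_nine_rows_in_order(self, preprocessed_small):
        split = kennard_stone(preprocessed_small.X, 0.7)
        report = run_grid(preprocessed_small, split, GridConfig(ga_seed=1))
        assert [(r.reduction, r.classifier) for r in report.rows] == GRID_ORDER
        assert report.best_row is not None

    def test_planted_cohort_classified_accurately(self, preprocessed_small):
        split = kennard_stone(preprocessed_small.X, 0.7)
        report = run_grid(preprocessed_small, split, GridConfig(ga_seed=1))
        for row in report.rows:
            assert row.status == "ok"
            assert row.accuracy >= 80.0, row.model_name

    def test_metrics_consistent_with_stored_counts(self, preprocessed_small):
        split = kennard_stone(preprocessed_small.X, 0.7)
        report = run_grid(preprocessed_small, split, GridConfig(ga_seed=1))
        for row in report.rows:
            c = row.counts
            assert row.accuracy == pytest.approx(100.0 * (c.TP + c.TN) / c.total)

    def test_failed_combination_does_not_abort_grid(self):
        # a constant matrix breaks PCA; SPA/GA/LDA columns also degenerate,
        # but the grid must still return nine annotated rows
        X = np.ones((12, 4))
        matrix = SpectralMatrix(
            X=X,
            mz_axis=np.arange(4),
            sample_ids=[f"s{i}" for i in range(12)],
            labels=np.asarray(["CG"] * 6 + ["FG"] * 6, dtype=object),
        )
        from fibropsi.partition import SplitIndices

        split = SplitIndices(list(range(8)), list(range(8, 12)))
        report = run_grid(matrix, split, GridConfig())
        assert len(report.rows) == 9
        assert any(r.status == "failed" for r in report.rows)

    def test_reductions_ignore_test_rows(self, preprocessed_small):
        """Leakage guard: scrambling the test rows leaves every fitted
        reduction (and hence its selected variables) unchanged."""
        split = kennard_stone(preprocessed_small.X, 0.7)
        report_a = run_grid(preprocessed_small, split, GridConfig(ga_seed=1))
        scrambled = preprocessed_small.select_rows(
            list(range(preprocessed_small.n_samples))
        )
        rng = np.random.default_rng(0)
        for i in split.test_idx:
            scrambled.X[i] = rng.permutation(scrambled.X[i])
        report_b = run_grid(scrambled, split, GridConfig(ga_seed=1))
        for ra, rb in zip(report_a.rows, report_b.rows):
            assert ra.selected_mz == rb.selected_mz
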