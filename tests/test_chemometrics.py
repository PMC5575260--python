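"""PCA, Fisher LDA, LOOCV, confusion metrics, ANOVA and Wilks' Lambda."""

import numpy as np
import pytest
from scipy import linalg as sla

from evraman.chemometrics import (
    ConfusionMatrix,
    anova_scores,
    confusion_metrics,
    fit_lda,
    fit_pca,
    loocv_classify,
    wilks_test,
)
from tests.conftest import small_cohort_config
from evraman.simulate import generate_dataset


class TestPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(10, 50))
        model = fit_pca(X, k=9)
        # independent oracle: eigendecomposition of the covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals = evals[::-1]
        total = evals.sum()
        assert np.allclose(model.var_fraction, evals[:9] / total, atol=1e-8)
        scores_oracle = Xc @ evecs[:, ::-1][:, :9]
        assert np.allclose(np.abs(model.scores), np.abs(scores_oracle), atol=1e-8)

    def test_identical_rows_give_zero_scores(self):
        X = np.tile(np.arange(5.0), (4, 1))
        model = fit_pca(X, k=2)
        assert np.allclose(model.scores, 0.0, atol=1e-12)
        assert np.allclose(model.var_fraction, 0.0)

    def test_two_spectra_one_direction(self):
        X = np.array([[1.0, 0.0, 2.0], [3.0, 1.0, 0.0]])
        model = fit_pca(X, k=1)
        assert model.var_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        X = rng.normal(size=(12, 30))
        k = 11
        model = fit_pca(X, k=k)
        assert np.allclose(model.loadings @ model.loadings.T, np.eye(k), atol=1e-8)
        assert np.allclose(model.reconstruct(model.scores), X, atol=1e-8)
        # fractions over all n-1 components sum to 1
        assert model.var_fraction.sum() == pytest.approx(1.0, abs=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(5, 10)), k=5)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(8, 20))
        model = fit_pca(X, k=3)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0


class TestLDA:
    def test_separated_point_classes(self):
        X = np.array([[-1.0], [-1.0], [-1.0], [1.0], [1.0], [1.0]])
        y = ["a", "a", "a", "b", "b", "b"]
        model = fit_lda(X, y)
        assert model.wilks_lambda < 1e-6
        assert list(model.predict(X)) == y

    def test_relabelled_identical_distributions(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0],
                      [0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        y = ["a", "a", "a", "b", "b", "b"]
        model = fit_lda(X, y)
        assert model.wilks_lambda == pytest.approx(1.0, abs=1e-9)

    def test_first_discriminant_matches_grid_search(self, rng):
        # 2-D, 3 classes: compare with a dense search over directions
        # maximising the Fisher ratio v'Bv / v'Wv
        centers = np.array([[0.0, 0.0], [2.0, 1.0], [1.0, 3.0]])
        X, y = [], []
        for c, mu in zip("abc", centers):
            pts = mu + 0.3 * rng.normal(size=(30, 2))
            X.append(pts)
            y += [c] * 30
        X = np.vstack(X)
        model = fit_lda(X, y)

        labels = np.asarray(y, object)
        grand = X.mean(axis=0)
        W = np.zeros((2, 2))
        B = np.zeros((2, 2))
        for c in "abc":
            Xc = X[labels == c]
            mc = Xc.mean(axis=0)
            W += (Xc - mc).T @ (Xc - mc)
            B += len(Xc) * np.outer(mc - grand, mc - grand)
        thetas = np.deg2rad(np.arange(0.0, 180.0, 0.02))
        vs = np.stack([np.cos(thetas), np.sin(thetas)])
        ratios = np.einsum("id,de,ie->i", vs.T, B, vs.T) / \
            np.einsum("id,de,ie->i", vs.T, W, vs.T)
        v_best = vs[:, np.argmax(ratios)]
        v_ours = model.discriminants[0]
        angle = np.rad2deg(np.arccos(min(1.0, abs(float(v_best @ v_ours)))))
        assert angle < 1.0

    def test_singleton_class_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(X, ["a", "a", "b"])

    def test_singular_scatter_needs_ridge(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_lda(X, ["a", "a", "b", "b"], ridge=0.0)


class TestLOOCV:
    def test_matches_naive_refit_oracle(self):
        d, _ = generate_dataset(small_cohort_config(3, n_per_class=10,
                                                    noise_sd=0.05))
        n_pcs = 8
        ours = loocv_classify(d, n_pcs=n_pcs, mode="paper")

        # independent oracle: assemble scatter matrices and refit per fold
        X = d.matrix
        labels = np.asarray(d.labels, object)
        pca = fit_pca(X, n_pcs)
        S = pca.scores
        preds = []
        for i in range(len(labels)):
            keep = np.arange(len(labels)) != i
            St, yt = S[keep], labels[keep]
            classes = sorted(set(yt))
            grand = St.mean(axis=0)
            W = np.zeros((n_pcs, n_pcs))
            B = np.zeros((n_pcs, n_pcs))
            means = {}
            for c in classes:
                Sc = St[yt == c]
                means[c] = Sc.mean(axis=0)
                W += (Sc - means[c]).T @ (Sc - means[c])
                B += len(Sc) * np.outer(means[c] - grand, means[c] - grand)
            evals, evecs = sla.eigh(B, W + 1e-8 * np.eye(n_pcs))
            A = evecs[:, np.argsort(evals)[::-1][:len(classes) - 1]]
            z = S[i] @ A
            dists = {c: np.linalg.norm(z - means[c] @ A) for c in classes}
            preds.append(min(sorted(dists), key=lambda c: dists[c]))
        oracle = ConfusionMatrix.from_predictions(labels, preds, ours.classes)
        assert np.array_equal(ours.counts, oracle.counts)

    def test_row_sums_are_class_counts(self, preprocessed_cohort):
        d, _ = preprocessed_cohort
        cm = loocv_classify(d, n_pcs=25)
        labels = np.asarray(d.labels, object)
        for c, rs in zip(cm.classes, cm.row_sums()):
            assert rs == np.sum(labels == c)

    def test_duplicated_classes_confused(self):
        # one class an exact copy of another: near-chance confusion between them
        d, _ = generate_dataset(small_cohort_config(5, n_per_class=12,
                                                    noise_sd=0.0,
                                                    separation=1.0))
        X = d.matrix.copy()
        labels = np.asarray(d.labels, object).copy()
        asc = X[labels == "ASC"]
        X[labels == "DF"] = asc[: np.sum(labels == "DF")]
        cm = loocv_classify(X, labels, n_pcs=5)
        i, j = cm.classes.index("ASC"), cm.classes.index("DF")
        cross = cm.counts[i, j] + cm.counts[j, i]
        assert cross > 0  # the duplicated pair cannot be separated

    def test_strict_mode_runs_and_preserves_row_sums(self):
        d, _ = generate_dataset(small_cohort_config(7, n_per_class=8))
        cm = loocv_classify(d, n_pcs=5, mode="strict")
        assert cm.total == d.n_spectra

    def test_singleton_class_fold_rejected(self):
        X = np.vstack([np.eye(3), np.eye(3), [[5.0, 5.0, 5.0]]])
        y = ["a"] * 3 + ["b"] * 3 + ["c"]
        with pytest.raises(ValueError, match="vanish"):
            loocv_classify(X, y, n_pcs=2)


class TestConfusionMetrics:
    def test_published_style_three_class_table(self):
        cm = ConfusionMatrix(["BM-MSC", "ASC", "DF"],
                             [[46, 2, 2], [1, 97, 7], [1, 7, 35]])
        m = confusion_metrics(cm)
        assert m.sensitivity["BM-MSC"] == 92.0
        assert m.sensitivity["ASC"] == 92.4
        assert m.sensitivity["DF"] == 81.4
        assert m.macro_sensitivity == 88.6
        # one-vs-rest specificity: TN=146 of 148 true negatives
        assert m.specificity["BM-MSC"] == 98.6
        assert m.accuracy["BM-MSC"] == 97.0

    def test_perfect_diagonal(self):
        m = confusion_metrics(ConfusionMatrix(list("abc"), np.diag([5, 5, 5])))
        assert m.macro_sensitivity == m.macro_specificity == m.macro_accuracy == 100.0

    def test_two_class_hand_arithmetic(self):
        m = confusion_metrics(ConfusionMatrix(["x", "y"], [[8, 2], [3, 7]]))
        assert m.sensitivity == {"x": 80.0, "y": 70.0}
        assert m.specificity == {"x": 70.0, "y": 80.0}

    def test_empty_class_row_warns_and_macro_skips(self):
        cm = ConfusionMatrix(list("ab"), [[5, 0], [0, 0]])
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = confusion_metrics(cm)
        assert m.sensitivity["b"] is None
        assert m.macro_sensitivity == 100.0

    def test_rounding_half_up(self):
        # 25/200 -> 12.5 stays; 7/8 = 87.5; 0.05 boundary rounds up
        m = confusion_metrics(ConfusionMatrix(["x", "y"], [[781, 219], [0, 1000]]))
        assert m.sensitivity["x"] == 78.1
        m2 = confusion_metrics(ConfusionMatrix(["x", "y"], [[1, 7], [0, 8]]))
        assert m2.sensitivity["x"] == 12.5


class TestAnova:
    def test_hand_computed_sums_of_squares(self):
        scores = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], float)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = anova_scores(scores, labels)
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_all_identical_values(self):
        res = anova_scores(np.ones(9), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.F == 0.0

    def test_zero_within_group_variance_flagged(self):
        res = anova_scores(np.array([0, 0, 1, 1.0]), ["a", "a", "b", "b"])
        assert np.isinf(res.F) and res.infinite and res.p == 0.0

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            anova_scores(np.arange(3.0), ["a", "a", "b"])


class TestWilks:
    def test_identical_distributions(self):
        X = np.vstack([np.eye(3) + 0.1, np.eye(3) + 0.1])
        y = ["a"] * 3 + ["b"] * 3
        res = wilks_test(X[:, :2], y)
        assert res.lam == pytest.approx(1.0, abs=1e-9)
        assert res.p > 0.9

    def test_separated_tight_classes(self, rng):
        X = np.vstack([rng.normal(0, 0.01, size=(20, 2)),
                       rng.normal(10, 0.01, size=(20, 2))])
        y = ["a"] * 20 + ["b"] * 20
        res = wilks_test(X, y)
        assert res.lam < 0.01 and res.p < 0.001

    def test_matches_determinant_oracle(self, rng):
        X = rng.normal(size=(30, 3))
        y = [("a", "b", "c")[i % 3] for i in range(30)]
        res = wilks_test(X, y)
        labels = np.asarray(y, object)
        grand = X.mean(axis=0)
        W = np.zeros((3, 3))
        B = np.zeros((3, 3))
        for c in "abc":
            Xc = X[labels == c]
            mc = Xc.mean(axis=0)
            W += (Xc - mc).T @ (Xc - mc)
            B += len(Xc) * np.outer(mc - grand, mc - grand)
        lam_oracle = np.linalg.det(W) / np.linalg.det(W + B)
        assert res.lam == pytest.approx(lam_oracle, abs=1e-10)
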