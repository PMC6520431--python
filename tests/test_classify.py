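"""LDA fitting/prediction, threshold metrics, and LOSO evaluation."""

import numpy as np
import pytest

from attnbci.classify import (
    best_threshold_sens_spec,
    decision_scores,
    fit_lda,
    loso_evaluate,
    predict,
    single_feature_loso,
)
from attnbci.features import FeatureMatrix
from attnbci.selection import SelectionConfig
from conftest import null_feature_matrix


class TestFitPredict:
    def test_1d_equal_variance_threshold_at_midpoint(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0.0, 1.0, 500)
        x1 = rng.normal(2.0, 1.0, 500)
        X = np.concatenate([x0, x1])[:, None]
        y = np.array(["easy"] * 500 + ["hard"] * 500)
        model = fit_lda(X, y)
        s = decision_scores(model, np.linspace(-1, 3, 401)[:, None])
        crossing = np.interp(0.0, s, np.linspace(-1, 3, 401))
        midpoint = (x0.mean() + x1.mean()) / 2.0
        assert crossing == pytest.approx(midpoint, abs=1e-6)

    def test_discriminant_direction_matches_closed_form(self):
        rng = np.random.default_rng(1)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.standard_normal((400, 2)) @ L.T
        X1 = rng.standard_normal((400, 2)) @ L.T + np.array([1.5, -1.0])
        X = np.vstack([X0, X1])
        y = np.array(["easy"] * 400 + ["hard"] * 400)
        model = fit_lda(X, y, ridge=0.0)
        w = np.linalg.solve(model.pooled_cov, model.class_means[1] - model.class_means[0])
        w_closed = np.linalg.solve(model.pooled_cov, model.class_means[1] - model.class_means[0])
        # direction from score gradient: scores are affine, recover w from two points
        e = np.eye(2)
        s0 = decision_scores(model, np.zeros((1, 2)))[0]
        grad = np.array([decision_scores(model, e[[i]])[0] - s0 for i in range(2)])
        np.testing.assert_allclose(
            grad / np.linalg.norm(grad), w_closed / np.linalg.norm(w_closed), atol=1e-6
        )
        np.testing.assert_allclose(w, w_closed)

    def test_agrees_with_sklearn_lda_predictions(self):
        """Cross-check the classifier against an independent implementation."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(2)
        X = rng.standard_normal((300, 5))
        y = np.where(X[:, 0] + 0.5 * rng.standard_normal(300) > 0, "hard", "easy")
        model = fit_lda(X, y, ridge=0.0)
        pred, _ = predict(model, X)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        agree = (pred == sk.predict(X)).mean()
        assert agree > 0.99

    def test_duplicated_columns_need_ridge(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = np.column_stack([x, x])
        y = np.array(["easy", "hard"] * 50)
        model = fit_lda(X, y, ridge=1e-6)  # must not raise
        pred, _ = predict(model, X)
        assert len(pred) == 100

    def test_well_separated_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (50, 3)), rng.normal(5, 0.1, (50, 3))])
        y = np.array(["easy"] * 50 + ["hard"] * 50)
        model = fit_lda(X, y)
        pred, _ = predict(model, X)
        assert (pred == y).all()

    def test_equal_means_classes_score_chance_on_fresh_draws(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((400, 4))
        y = np.array(["easy", "hard"] * 200)
        model = fit_lda(X, y)
        Xnew = rng.standard_normal((2000, 4))
        ynew = np.array(["easy", "hard"] * 1000)
        pred, _ = predict(model, Xnew)
        assert (pred == ynew).mean() == pytest.approx(0.5, abs=0.05)

    def test_scores_invariant_to_consistent_rescaling(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((200, 3))
        y = np.where(X[:, 0] > 0, "hard", "easy")
        scale = np.array([10.0, 0.1, 3.0])
        m1 = fit_lda(X, y, ridge=0.0)
        m2 = fit_lda(X * scale, y, ridge=0.0)
        s1 = decision_scores(m1, X)
        s2 = decision_scores(m2, X * scale)
        np.testing.assert_allclose(s1, s2, rtol=1e-8, atol=1e-8)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(np.zeros((3, 2)), np.array(["easy", "easy", "hard"]))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        model = fit_lda(rng.standard_normal((40, 3)), np.array(["easy", "hard"] * 20))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, rng.standard_normal((5, 4)))


class TestBestThreshold:
    def test_perfect_separation(self):
        s = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array(["easy", "easy", "hard", "hard"])
        assert best_threshold_sens_spec(s, y, "hard") == (1.0, 1.0)

    def test_identical_distributions_balanced_accuracy_near_half(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(2000)
        y = np.array(["easy", "hard"] * 1000)
        sens, spec = best_threshold_sens_spec(s, y, "hard")
        assert (sens + spec) / 2 == pytest.approx(0.5, abs=0.05)

    def test_matches_exhaustive_midpoint_sweep(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(60)
        y = rng.choice(["easy", "hard"], 60)
        if len(set(y)) < 2:
            y[0] = "easy"; y[1] = "hard"
        sens, spec = best_threshold_sens_spec(s, y, "hard")
        pos = y == "hard"
        best = -1.0
        for t in np.concatenate([s - 1e-9, s + 1e-9]):
            called = s >= t
            se = (called & pos).sum() / pos.sum()
            sp = (~called & ~pos).sum() / (~pos).sum()
            best = max(best, (se + sp) / 2)
        assert (sens + spec) / 2 == pytest.approx(best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            best_threshold_sens_spec(np.arange(4.0), np.array(["easy"] * 4), "hard")


class TestLoso:
    def test_fold_count_and_complete_coverage(self):
        fm = null_feature_matrix(0, n_subjects=4, n_epochs=20, n_features=5)
        rep = loso_evaluate(fm, "easy-hard", SelectionConfig(seed=0, max_features=3),
                            k_grid=[1, 2])
        assert len(rep.subjects) == 4
        assert rep.fold_accuracy.shape == (4, 2)

    def test_informative_feature_gives_high_transfer_accuracy(self):
        rng = np.random.default_rng(10)
        fm = null_feature_matrix(10, n_subjects=6, n_epochs=40, n_features=8)
        sep = np.where(fm.labels == "hard", 4.0, 0.0) + rng.standard_normal(fm.n_epochs)
        fm.values[:, 0] = sep
        rep = loso_evaluate(fm, "easy-hard", SelectionConfig(seed=1, max_features=5),
                            k_grid=[1, 2, 3])
        assert rep.mean_accuracy > 0.95

    def test_subject_specific_sign_flips_do_not_transfer(self):
        """A feature informative only within subjects yields chance LOSO accuracy
        while within-subject accuracy is far above chance (leakage control)."""
        rng = np.random.default_rng(11)
        n_subj, n_ep = 8, 40
        fm = null_feature_matrix(11, n_subjects=n_subj, n_epochs=n_ep, n_features=6)
        y_num = np.where(fm.labels == "hard", 1.0, -1.0)
        signs = np.repeat(np.where(np.arange(n_subj) % 2 == 0, 1.0, -1.0), n_ep)
        fm.values[:, 0] = 2.0 * y_num * signs + 0.3 * rng.standard_normal(fm.n_epochs)
        rep = loso_evaluate(fm, "easy-hard", SelectionConfig(seed=2, max_features=4),
                            k_grid=[1, 2])
        assert rep.fold_accuracy.mean() < 0.65  # no cross-subject transfer

        within = []
        for s in sorted(set(fm.subject_ids)):
            idx = np.flatnonzero(fm.subject_ids == s)
            train, test = idx[::2], idx[1::2]  # stratified: labels alternate
            model = fit_lda(fm.values[train][:, [0]], fm.labels[train])
            pred, _ = predict(model, fm.values[test][:, [0]])
            within.append((pred == fm.labels[test]).mean())
        assert np.mean(within) > 0.9

    def test_absent_class_rejected(self):
        fm = null_feature_matrix(12, n_subjects=3, n_epochs=20, n_features=4,
                                 classes=("easy", "hard"))
        with pytest.raises(ValueError):
            loso_evaluate(fm, "easy-medium")

    def test_single_feature_map_has_one_accuracy_per_feature(self):
        fm = null_feature_matrix(13, n_subjects=3, n_epochs=20, n_features=6)
        acc = single_feature_loso(fm, "easy-hard")
        assert len(acc) == 6
        assert ((acc >= 0) & (acc <= 1)).all()
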