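import numpy as np
import pytest

from chemurin import (
    DAPCModel,
    fit_dapc,
    fit_dapc_pipeline,
    fit_pca,
    manova_significance,
    predict,
    top_loadings,
)
from chemurin.chemometrics import annotate_band
from chemurin.errors import SingularScatterError


def structured_matrix(n=22, p=50, variances=(40, 25, 15, 10, 5, 4), tail=1.0,
                      seed=5):
    """Data with exactly known sample covariance spectrum.

    Columns of the score matrix are orthonormalized and mean-centered, so the
    sample covariance is exactly diag(variances + tail split over the rest).
    """
    rng = np.random.default_rng(seed)
    k = len(variances) + 4
    var = list(variances) + [tail / 4.0] * 4
    Z = rng.normal(size=(n, k))
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    V, _ = np.linalg.qr(rng.normal(size=(p, k)))
    X = Q * np.sqrt(np.array(var) * (n - 1)) @ V.T
    return X


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=12)
        v = rng.normal(size=30)
        X = 5.0 + np.outer(t, v)
        model = fit_pca(X, retention=0.99)
        assert model.n_selected == 1
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(model.variance_fractions[1:] < 1e-12)

    def test_retention_rule_crosses_at_six(self):
        # six directions carry 99% of the variance; the rest is split small
        X = structured_matrix()
        model = fit_pca(X, retention=0.99)
        assert model.n_selected == 6
        cum = np.cumsum(model.variance_fractions)
        assert cum[4] < 0.99 <= cum[5] + 1e-9

    def test_reconstruction_with_all_components(self):
        X = structured_matrix(n=15, p=20)
        model = fit_pca(X, retention=1.0)
        scores = (X - model.mean_row) @ model.loadings
        back = model.mean_row + scores @ model.loadings.T
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_loadings_orthonormal(self):
        X = structured_matrix(n=18, p=25)
        model = fit_pca(X)
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-9)

    def test_sign_convention(self):
        X = structured_matrix(n=12, p=16)
        model = fit_pca(X)
        for j in range(model.loadings.shape[1]):
            col = model.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_variance_fractions_monotone(self):
        model = fit_pca(structured_matrix())
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)
        assert model.variance_fractions.sum() <= 1 + 1e-9

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 5)))


class TestManova:
    def test_no_separation_gives_lambda_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        scores = np.vstack([pts, pts])  # identical class distributions
        labels = ["a"] * 6 + ["b"] * 6
        lam, dims = manova_significance(scores, labels)
        assert lam == pytest.approx(1.0, abs=1e-9)
        assert dims == 0

    def test_strong_separation_gives_lambda_near_zero(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3)) + 100.0
        lam, dims = manova_significance(np.vstack([a, b]), ["a"] * 8 + ["b"] * 8)
        assert lam < 1e-3
        assert dims == 1

    def test_matches_determinant_ratio_oracle(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        lam, _ = manova_significance(scores, labels)
        # independent oracle: explicit det(W)/det(T)
        grand = scores.mean(axis=0)
        W = np.zeros((3, 3))
        for lab in ("a", "b"):
            sub = scores[np.array(labels) == lab]
            d = sub - sub.mean(axis=0)
            W += d.T @ d
        T = (scores - grand).T @ (scores - grand)
        assert lam == pytest.approx(np.linalg.det(W) / np.linalg.det(T), rel=1e-9)

    def test_matches_statsmodels_wilks(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(4)
        scores = rng.normal(size=(12, 2))
        scores[6:] += [1.5, -0.5]
        labels = ["a"] * 6 + ["b"] * 6
        lam, _ = manova_significance(scores, labels)
        mv = MANOVA(scores, np.column_stack([
            np.ones(12), [0] * 6 + [1] * 6
        ]))
        table = mv.mv_test([("grp", np.array([[0.0, 1.0]]))])
        ref = table.results["grp"]["stat"].loc["Wilks' lambda", "Value"]
        assert lam == pytest.approx(float(ref), rel=1e-8)

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(8, 7))
        with pytest.raises(SingularScatterError):
            manova_significance(scores, ["a"] * 4 + ["b"] * 4)


class TestDAPC:
    def two_class_scores(self, n=8, gap=6.0, seed=0, p=2):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, p), scale=0.5)
        b = rng.normal(size=(n, p), scale=0.5)
        a[:, 0] -= gap / 2
        b[:, 0] += gap / 2
        return np.vstack([a, b]), ["A"] * n + ["B"] * n

    def test_canonical_one_aligns_with_separating_axis(self):
        # isotropic within-class scatter, separation purely along axis 1:
        # the whitened eigenproblem must return axis 1 as Canonical 1
        block = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        scores = np.vstack([block + [-3.0, 0.0], block + [3.0, 0.0]])
        labels = ["A"] * 4 + ["B"] * 4
        model = fit_dapc(scores, labels)
        axis = model.canonical_coefficients[:, 0]
        cosine = abs(axis[0]) / np.linalg.norm(axis)
        assert cosine >= 0.99

    def test_all_axes_retained_with_trailing_zero_eigenvalues(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=(20, 6))
        scores[10:, 0] += 8.0
        model = fit_dapc(scores, ["A"] * 10 + ["B"] * 10)
        assert model.n_canonicals == 6
        assert model.eigenvalues[0] > 1.0
        assert np.all(model.eigenvalues[1:] < 1e-8 * model.eigenvalues[0])

    def test_centroids_match_bruteforce_projected_means(self):
        scores, labels = self.two_class_scores(p=4, gap=3.0, seed=7)
        model = fit_dapc(scores, labels)
        coords = scores @ model.canonical_coefficients
        labels = np.asarray(labels)
        for i, lab in enumerate(model.class_labels):
            np.testing.assert_allclose(
                model.centroids[i], coords[labels == lab].mean(axis=0), atol=1e-9
            )

    def test_rotation_of_scores_leaves_predictions_invariant(self):
        scores, labels = self.two_class_scores(p=4, gap=2.5, seed=8)
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        m1 = fit_dapc(scores, labels)
        m2 = fit_dapc(scores @ Q, labels)
        p1 = [m1.predict_rows(row)[0][0] for row in scores]
        p2 = [m2.predict_rows(row @ Q)[0][0] for row in scores]
        assert p1 == p2


class TestPredict:
    def pipeline_model(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 9), scale=0.4)
        X[6:, 3] += 5.0
        labels = ["A"] * 6 + ["B"] * 6
        return fit_dapc_pipeline(X, labels), X, labels

    def test_training_rows_match_bruteforce_nearest_centroid(self):
        model, X, labels = self.pipeline_model()
        preds, coords = model.predict_rows(X)
        for i in range(X.shape[0]):
            d = np.linalg.norm(coords[i] - model.centroids, axis=1)
            assert preds[i] == model.class_labels[int(np.argmin(d))]
        assert preds == labels  # well separated

    def test_equidistant_point_breaks_tie_to_first_label(self):
        # symmetric 1-D problem: the midpoint is exactly equidistant
        X = np.array([[-3.0], [-1.0], [1.0], [3.0]])
        labels = ["A", "A", "B", "B"]
        model = fit_dapc_pipeline(X, labels)
        lab, _ = predict(model, np.array([0.0]))
        assert lab == "A"

    def test_grid_mismatch_error(self):
        model, X, _ = self.pipeline_model()
        with pytest.raises(ValueError, match="grid"):
            model.predict_rows(np.ones(4))


class TestTopLoadings:
    def test_single_feature_dominates(self):
        rng = np.random.default_rng(11)
        t = rng.normal(size=10)
        X = np.zeros((10, 6))
        X[:, 2] = t  # all variance at one grid point
        grid = np.array([400.0, 500.0, 600.0, 700.0, 800.0, 900.0])
        X[:5, 2] -= 3.0
        X[5:, 2] += 3.0
        model = fit_dapc_pipeline(X, ["A"] * 5 + ["B"] * 5, grid=grid)
        top = top_loadings(model, ("canonical", 0), k=1)
        assert top[0][0] == 600.0

    def test_urea_band_effect_recovered(self, grid400):
        # classes differ only in the urea band's amplitude relative to a
        # fixed reference band, surviving unit-norm scaling
        rng = np.random.default_rng(12)
        urea = np.exp(-0.5 * ((grid400 - 1002.0) / 6.0) ** 2)
        ref = np.exp(-0.5 * ((grid400 - 1450.0) / 8.0) ** 2)
        rows, labels = [], []
        for i in range(16):
            scale = 1.0 + rng.normal(0, 0.1)  # overall intensity nuisance
            amp = 1.8 if i < 8 else 1.0
            y = scale * (amp * urea + ref) + rng.normal(0, 0.005, size=grid400.size)
            rows.append(y / np.linalg.norm(y))
            labels.append("A" if i < 8 else "B")
        model = fit_dapc_pipeline(np.array(rows), labels, grid=grid400)
        top3 = [w for w, _, _ in top_loadings(model, ("canonical", 0), k=3)]
        assert any(abs(w - 1002.0) <= 6.0 for w in top3)

    def test_annotation_join_at_1004(self):
        assert "protein" in annotate_band(1004.0)
        assert "urea" in annotate_band(1004.0)  # 1002 within +-5
        assert annotate_band(1550.0) == ""

    def test_k_clamped_with_warning(self):
        model, _, _ = TestPredict().pipeline_model()
        with pytest.warns(UserWarning, match="clamp"):
            out = top_loadings(model, ("pc", 0), k=99)
        assert len(out) == 9


class TestSerialization:
    def test_round_trip_is_exact(self, tmp_path):
        model, _, _ = TestPredict().pipeline_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DAPCModel.from_json(path)
        np.testing.assert_array_equal(back.pc_model.loadings, model.pc_model.loadings)
        np.testing.assert_array_equal(back.pc_model.mean_row, model.pc_model.mean_row)
        np.testing.assert_array_equal(
            back.canonical_coefficients, model.canonical_coefficients
        )
        np.testing.assert_array_equal(back.centroids, model.centroids)
        assert back.class_labels == model.class_labels
        assert back.pc_model.n_selected == model.pc_model.n_selected

    def test_version_checked(self, tmp_path):
        model, _, _ = TestPredict().pipeline_model()
        text = model.to_json()
        bad = text.replace('"version": 1', '"version": 99')
        with pytest.raises(ValueError, match="version"):
            DAPCModel.from_json(bad)
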