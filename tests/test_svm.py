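"""SVM module: flattening, train-only reductions, fitting, calibration, tuning."""

import numpy as np
import pytest

from morphsev.svm import (
    SVMConfig,
    fit_reduction,
    flatten,
    log_bins,
    predict_proba_svm,
    sample_configs,
    train_svm,
    tune_svm,
    unflatten,
    weighted_hinge_loss,
)


class TestFlatten:
    def test_column_count(self, rng):
        vols = rng.normal(size=(3, 2, 2, 2))
        assert flatten(vols).shape == (3, 8)

    def test_round_trip(self, rng):
        vols = rng.normal(size=(4, 3, 4, 5))
        assert np.array_equal(unflatten(flatten(vols), (3, 4, 5)), vols)

    def test_column_coordinate_oracle(self, rng):
        vols = rng.normal(size=(2, 3, 4, 5))
        table = flatten(vols)
        for j in (0, 7, 19, 59):
            coord = np.unravel_index(j, (3, 4, 5))
            assert table[1, j] == vols[1][coord]


class TestReduction:
    def test_exact_planar_data_reconstructed(self, rng):
        basis = rng.normal(size=(2, 20))
        coeffs = rng.normal(size=(30, 2))
        data = coeffs @ basis + rng.normal(size=20)  # offset plane
        proj = fit_reduction(data, "pca", 2)
        z = proj.transform(data)
        recon = z @ proj.pca_.components_ + proj.pca_.mean_
        assert np.allclose(recon, data, atol=1e-8)

    def test_pca_variances_non_increasing(self, rng):
        data = rng.normal(size=(40, 10)) * np.arange(1, 11)
        proj = fit_reduction(data, "pca", 5)
        v = proj.transform(data).var(axis=0)
        assert (np.diff(v) <= 1e-9).all()

    def test_held_out_projection_matches_eigendecomposition(self, rng):
        train = rng.normal(size=(25, 8))
        held = rng.normal(size=(4, 8))
        proj = fit_reduction(train, "pca", 3)
        # independent oracle: eigendecomposition of the training covariance
        mu = train.mean(axis=0)
        cov = (train - mu).T @ (train - mu) / (len(train) - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][:3]
        loadings = vecs[:, order]
        expected = (held - mu) @ loadings
        got = proj.transform(held)
        for k in range(3):  # eigenvector signs are arbitrary
            assert np.allclose(got[:, k], expected[:, k], atol=1e-8) or np.allclose(
                got[:, k], -expected[:, k], atol=1e-8
            )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_reduction(rng.normal(size=(5, 3)), "pca", 5)

    def test_no_leakage_poisoning(self, rng):
        """Projector statistics must be unaffected by test-row contents."""
        train = rng.normal(size=(20, 6))
        proj = fit_reduction(train, "pca", 2, seed=0)
        clean = rng.normal(size=(3, 6))
        z1 = proj.transform(clean)
        proj2 = fit_reduction(train, "pca", 2, seed=0)
        z2 = proj2.transform(clean)
        # refit after "seeing" poisoned rows changes nothing: fit takes train only
        _ = proj2.transform(np.full((3, 6), 1e9))
        assert np.array_equal(z1, z2)
        assert np.array_equal(proj2.transform(clean), z2)

    def test_ica_runs_on_pca_components(self, rng):
        s = rng.laplace(size=(200, 3))
        mixing = rng.normal(size=(3, 10))
        data = s @ mixing
        proj = fit_reduction(data, "ica", 3, seed=0)
        z = proj.transform(data)
        assert z.shape == (200, 3)


class TestTrainAndCalibrate:
    def test_separable_linear(self, rng):
        x = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_svm(x, y, SVMConfig(kernel="linear", cost=100.0))
        assert (model.predict(x) == y).all()

    def test_xor_needs_rbf(self, rng):
        pts = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]] * 10) + rng.normal(
            0, 0.05, (40, 2)
        )
        y = np.array([0, 0, 1, 1] * 10)
        rbf = train_svm(pts, y, SVMConfig(kernel="rbf", cost=10.0, kernel_scale=1.0))
        lin = train_svm(pts, y, SVMConfig(kernel="linear", cost=10.0))
        assert (rbf.predict(pts) == y).mean() == 1.0
        assert (lin.predict(pts) == y).mean() <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((5, 2)), np.zeros(5), SVMConfig())

    def test_probability_monotone_in_decision_value(self, rng):
        x = np.vstack([rng.normal(-1, 0.6, (30, 2)), rng.normal(1, 0.6, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = train_svm(x, y, SVMConfig(kernel="linear", cost=1.0))
        grid = rng.normal(0, 2, (50, 2))
        f = model.decision_values(grid)
        p = predict_proba_svm(model, grid)[:, 1]
        order = np.argsort(f)
        assert (np.diff(p[order]) >= -1e-12).all()
        assert np.allclose(predict_proba_svm(model, grid).sum(axis=1), 1.0)

    def test_calibration_recovers_slope_sign(self, rng):
        """On toy logistic data the fitted sigmoid is increasing (a > 0)."""
        f = rng.normal(0, 2, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-2 * f))).astype(int)
        from morphsev.svm import _fit_platt

        a, b = _fit_platt(f, y)
        assert a > 0

    def test_spatial_blindness_under_permutation(self, rng):
        """Linear-kernel predictions are invariant to a consistent voxel shuffle."""
        x = rng.normal(size=(40, 27))
        y = (x[:, :5].sum(axis=1) > 0).astype(int)
        perm = rng.permutation(27)
        m1 = train_svm(x, y, SVMConfig(kernel="linear", cost=1.0))
        m2 = train_svm(x[:, perm], y, SVMConfig(kernel="linear", cost=1.0))
        test = rng.normal(size=(10, 27))
        assert np.allclose(
            m1.decision_values(test), m2.decision_values(test[:, perm]), atol=1e-6
        )


class TestTuning:
    def test_log_bins_span_stated_ranges(self):
        c = log_bins(1e-3, 2e4)
        assert len(c) == 300 and np.isclose(c[0], 1e-3) and np.isclose(c[-1], 2e4)

    def test_single_draw_returned(self, rng):
        x = np.vstack([rng.normal(-1, 0.5, (16, 3)), rng.normal(1, 0.5, (16, 3))])
        y = np.array([0] * 16 + [1] * 16)
        folds = [(np.arange(0, 24), np.arange(24, 32))]
        cfg = tune_svm(x, y, folds, SVMConfig(kernel="linear", seed=0), n_draws=1)
        assert cfg.kernel == "linear"

    def test_draws_respect_component_bounds(self, rng):
        cfgs = sample_configs(SVMConfig(reduction="pca"), 50, rng)
        for c in cfgs:
            assert 1 <= c.n_components <= 75
            assert 1e-3 <= c.cost <= 2e4
            assert 1e-3 <= c.kernel_scale <= 1e3

    def test_recovers_better_cost_on_noisy_separable_data(self, rng):
        """Config chosen by tuning matches the exhaustive argmin over draws."""
        x = np.vstack([rng.normal(-0.6, 1.0, (30, 4)), rng.normal(0.6, 1.0, (30, 4))])
        y = np.array([0] * 30 + [1] * 30)
        idx = rng.permutation(60)
        x, y = x[idx], y[idx]
        folds = [(np.arange(0, 40), np.arange(40, 60)), (np.arange(20, 60), np.arange(0, 20))]
        base = SVMConfig(kernel="linear", seed=3)
        chosen = tune_svm(x, y, folds, base, n_draws=8)
        # exhaustive oracle over the same draws
        draws = sample_configs(base, 8, np.random.default_rng(3))
        losses = []
        for c in draws:
            fl = []
            for tr, he in folds:
                m = train_svm(x[tr], y[tr], c)
                w = len(tr) / (2.0 * np.bincount(y[tr], minlength=2))
                fl.append(weighted_hinge_loss(m.decision_values(x[he]), y[he], w))
            losses.append(np.mean(fl))
        best = draws[int(np.argmin(losses))]
        assert chosen.cost == best.cost and chosen.kernel_scale == best.kernel_scale


def test_hinge_loss_balanced_weights_match_plain_mean():
    decision = np.array([0.5, -2.0, 1.5, -0.2])
    labels = np.array([1, 0, 1, 0])
    w = np.array([1.0, 1.0])
    plain = np.mean(np.maximum(0, 1 - np.where(labels == 1, 1, -1) * decision))
    assert np.isclose(weighted_hinge_loss(decision, labels, w), plain)
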