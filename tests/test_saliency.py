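"""Attribution: Grad-CAM++ vs CAM oracle, Deep SHAP completeness, kernel SHAP
vs exhaustive Shapley, normalization conservation, ROI construction/stats."""

import math
from itertools import combinations

import numpy as np
import pytest

from morphsev import nnet
from morphsev.cnn import ArchitectureSpec, build_network
from morphsev.saliency import (
    ROIPartition,
    build_rois,
    deep_shap,
    gradcampp,
    kernel_shap,
    mean_performing_repeat,
    rectify_and_normalize,
    roi_group_test,
)


class _GapModel:
    """conv -> ReLU -> global average pool -> linear head (CAM oracle net).

    The CAM equivalence of gradient-weighted maps holds for channels with
    nonnegative head weights (negative channels are clipped by the ReLU on
    the gradients), so the target class's head weights are drawn nonnegative.
    """

    def __init__(self, seed=0, channels=6, shape=(8, 8, 8), target=1):
        rng = np.random.default_rng(seed)
        self.conv = nnet.Conv3d(1, channels, rng)
        self.head = nnet.Linear(channels, 2, rng)
        self.head.params["W"][target] = np.abs(self.head.params["W"][target])
        self.net = nnet.Sequential(
            [self.conv, nnet.ReLU(), nnet.GlobalAvgPool3d(), self.head]
        )
        self.last_conv_relu_index = 1
        self.input_shape = shape


class TestGradCAMpp:
    def test_matches_cam_on_gap_linear_head(self, rng):
        """For GAP + linear, the class-activation map is the closed-form
        oracle; Grad-CAM++ must align with it (cosine > 0.99)."""
        model = _GapModel()
        for trial in range(3):
            x = rng.normal(size=(8, 8, 8)).astype(np.float32)
            m = gradcampp(model, x, target_class=1)
            a = x[None, None]
            for layer in model.net.layers[:2]:
                a = layer.forward(a, False, None)
            w = model.head.params["W"][1]
            cam = np.maximum((w[:, None, None, None] * a[0]).sum(axis=0), 0.0)
            denom = np.linalg.norm(m.grid) * np.linalg.norm(cam)
            if denom == 0:
                continue
            cos = float(np.dot(m.grid.ravel(), cam.ravel()) / denom)
            assert cos > 0.99

    def test_zeroed_head_gives_zero_map(self):
        model = _GapModel()
        model.head.params["W"][:] = 0.0
        model.head.params["b"][:] = 0.0
        with pytest.warns(UserWarning):
            m = gradcampp(model, np.zeros((8, 8, 8), dtype=np.float32), 1)
        assert (m.grid == 0).all()

    def test_nonnegative_everywhere_and_upsampled_to_input(self, rng):
        spec = ArchitectureSpec(blocks=((1, 8), (1, 8)), dropout_rate=0.6)
        model = build_network(spec, (9, 10, 11), seed=0)
        m = gradcampp(model, rng.normal(size=(9, 10, 11)).astype(np.float32), 0)
        assert m.grid.shape == (9, 10, 11)
        assert (m.grid >= 0).all()


class TestDeepShap:
    def test_zero_attribution_at_background_sample(self, rng):
        spec = ArchitectureSpec(blocks=((1, 8),), dropout_rate=0.6)
        model = build_network(spec, (6, 6, 6), seed=1)
        x = rng.normal(size=(6, 6, 6)).astype(np.float32)
        attr = deep_shap(model, x, x[None], target_class=0)
        assert np.abs(attr).max() < 1e-6

    def test_linear_model_closed_form(self, rng):
        lin = nnet.Sequential([nnet.Flatten(), nnet.Linear(27, 2, rng)])
        x = rng.normal(size=(3, 3, 3)).astype(np.float32)
        bg = rng.normal(size=(5, 3, 3, 3)).astype(np.float32)
        attr = deep_shap(lin, x, bg, target_class=1)
        w = lin.layers[1].params["W"][1].reshape(3, 3, 3)
        expected = w * (x - bg.mean(axis=0))
        assert np.allclose(attr, expected, atol=1e-6)

    def test_completeness_through_conv_pool_bn_stack(self, rng):
        """Attributions sum to score(x) - mean background score."""
        spec = ArchitectureSpec(blocks=((2, 8), (1, 8)), dropout_rate=0.7)
        model = build_network(spec, (7, 8, 7), seed=2)
        x = rng.normal(size=(7, 8, 7)).astype(np.float32)
        bg = rng.normal(size=(4, 7, 8, 7)).astype(np.float32)
        attr = deep_shap(model, x, bg, target_class=1)
        score_x = model.net.forward(x[None, None], train=False)[0, 1]
        scores_b = [
            model.net.forward(b[None, None], train=False)[0, 1] for b in bg
        ]
        residual = abs(attr.sum() - (score_x - np.mean(scores_b)))
        scale = max(abs(score_x - np.mean(scores_b)), 1.0)
        assert residual < 1e-2 * scale


class TestKernelShap:
    def _oracle(self, f, x, data, k_fraction):
        """Exhaustive-coalition Shapley with the same kNN value function."""
        p = x.size
        k = max(1, round(k_fraction * len(data)))
        nb = data[np.argsort(np.linalg.norm(data - x, axis=1), kind="stable")[:k]]

        def value(S):
            comp = nb.copy()
            for j in S:
                comp[:, j] = x[j]
            return float(np.mean(f(comp)))

        phi = np.zeros(p)
        for i in range(p):
            others = [j for j in range(p) if j != i]
            for r in range(p):
                for S in combinations(others, r):
                    w = math.factorial(len(S)) * math.factorial(p - len(S) - 1)
                    phi[i] += w / math.factorial(p) * (value(S + (i,)) - value(S))
        return phi

    def test_additive_model_exact(self, rng):
        data = rng.normal(size=(30, 2))
        x = rng.normal(size=2)
        f = lambda t: t[:, 0] + t[:, 1]
        est = kernel_shap(f, x, data, k_fraction=0.1, n_draws=500, seed=0)
        oracle = self._oracle(f, x, data, 0.1)
        assert np.allclose(est, oracle, atol=1e-10)

    def test_nonlinear_4_feature_model_matches_oracle(self, rng):
        data = rng.normal(size=(40, 4))
        x = rng.normal(size=4)
        f = lambda t: t[:, 0] * t[:, 1] + np.tanh(t[:, 2]) - 0.5 * t[:, 3] ** 2
        est = kernel_shap(f, x, data, k_fraction=0.1, n_draws=5000, seed=0)
        oracle = self._oracle(f, x, data, 0.1)
        assert np.abs(est - oracle).max() < 1e-8  # exact enumeration regime

    def test_constant_model_zero_attributions(self, rng):
        data = rng.normal(size=(20, 3))
        est = kernel_shap(
            lambda t: np.full(len(t), 3.3), rng.normal(size=3), data, 0.2, 200, 0
        )
        assert np.allclose(est, 0.0, atol=1e-10)

    def test_exchangeable_features_get_equal_attribution(self, rng):
        data = np.tile(rng.normal(size=(25, 1)), (1, 2))  # identical columns
        x = np.array([0.7, 0.7])
        f = lambda t: t.sum(axis=1)
        est = kernel_shap(f, x, data, 0.2, 500, 0)
        assert est[0] == pytest.approx(est[1], abs=1e-10)


class TestRectifyNormalize:
    def test_arithmetic_example(self):
        m = rectify_and_normalize(np.array([-1.0, 1.0, 1.0]))
        assert np.allclose(m.grid, [0.0, 0.5, 0.5])
        assert m.normalized

    def test_nonnegative_map_scaled_by_total(self, rng):
        g = rng.random((3, 3, 3))
        m = rectify_and_normalize(g)
        assert np.allclose(m.grid, g / g.sum())
        assert m.grid.sum() == pytest.approx(1.0)

    def test_degenerate_all_zero_stays_zero(self):
        m = rectify_and_normalize(np.full((2, 2, 2), -1.0))
        assert (m.grid == 0).all() and not m.normalized


class TestROIs:
    def _setup(self, template):
        lesion = np.zeros(template.shape, dtype=bool)
        lesion[3:5, 6:9, 6:9] = True
        return lesion, template > 0

    def test_zero_radius_empty_perilesional(self, template_16):
        lesion, brain = self._setup(template_16)
        rois = build_rois(lesion, brain, dilation_radius=0)
        assert not rois.perilesional.any()

    def test_single_voxel_lesion_face_neighbors(self, template_24):
        lesion = np.zeros(template_24.shape, dtype=bool)
        lesion[6, 14, 12] = True
        brain = template_24 > 0
        rois = build_rois(lesion, brain, dilation_radius=1, connectivity=6)
        expected = set()
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            p = (6 + d[0], 14 + d[1], 12 + d[2])
            if brain[p] and p[0] < 12:
                expected.add(p)
        got = set(map(tuple, np.argwhere(rois.perilesional)))
        assert got == expected

    def test_masks_disjoint_and_left_three_tile_left_brain(self, template_16):
        lesion, brain = self._setup(template_16)
        rois = build_rois(lesion, brain, dilation_radius=2)
        masks = list(rois.as_dict().values())
        total = np.zeros(template_16.shape, dtype=int)
        for m in masks:
            total += m.astype(int)
        assert total.max() <= 1  # pairwise disjoint
        nx = template_16.shape[0]
        left_brain = brain.copy()
        left_brain[nx // 2 :] = False
        union_left = rois.lesion | rois.perilesional | rois.extralesional
        assert np.array_equal(union_left, left_brain)

    def test_homologs_are_midline_reflections(self, template_16):
        lesion, brain = self._setup(template_16)
        rois = build_rois(lesion, brain, dilation_radius=1)
        assert np.array_equal(
            rois.lesion_homolog, np.flip(rois.lesion, axis=0)
        )  # symmetric template: reflection stays in right-brain

    def test_right_hemisphere_lesion_rejected(self, template_16):
        lesion = np.zeros(template_16.shape, dtype=bool)
        lesion[12, 8, 8] = True
        with pytest.raises(ValueError):
            build_rois(lesion, template_16 > 0)


class TestROIGroupStats:
    def test_identical_maps_give_t_zero(self, template_16):
        lesion = np.zeros(template_16.shape, dtype=bool)
        lesion[3:5, 6:9, 6:9] = True
        brain = template_16 > 0
        rois = [build_rois(lesion, brain) for _ in range(6)]
        g = rectify_and_normalize(np.ones(template_16.shape)).grid
        df = roi_group_test([g] * 6, rois, np.array([1, 1, 1, 0, 0, 0]))
        assert np.allclose(df["t"], 0.0) and np.allclose(df["p"], 1.0)

    def test_planted_difference_detected_in_target_roi_only(self, template_16, rng):
        lesion = np.zeros(template_16.shape, dtype=bool)
        lesion[3:5, 6:9, 6:9] = True
        brain = template_16 > 0
        roi = build_rois(lesion, brain, dilation_radius=1)
        maps, groups, rois = [], [], []
        for i in range(16):
            g = rng.random(template_16.shape) * brain
            if i < 8:  # severe group: saliency concentrated in the lesion
                g[roi.lesion] += 30.0
            maps.append(rectify_and_normalize(g).grid)
            groups.append(1 if i < 8 else 0)
            rois.append(roi)
        df = roi_group_test(maps, rois, np.array(groups)).set_index("roi")
        assert df.loc["lesion", "p"] < 1e-4 and df.loc["lesion", "t"] > 0

    def test_normalization_conservation_over_partition(self, template_16, rng):
        """ROI sums plus the out-of-mask remainder reconstruct 1 exactly."""
        lesion = np.zeros(template_16.shape, dtype=bool)
        lesion[3:5, 6:9, 6:9] = True
        brain = template_16 > 0
        roi = build_rois(lesion, brain, dilation_radius=2)
        g = rectify_and_normalize(rng.random(template_16.shape)).grid
        covered = np.zeros(template_16.shape, dtype=bool)
        total = 0.0
        for mask in roi.as_dict().values():
            total += g[mask].sum()
            covered |= mask
        assert total + g[~covered].sum() == pytest.approx(1.0)

    def test_small_group_rejected(self, template_16):
        with pytest.raises(ValueError):
            roi_group_test([], [], np.array([1, 0]))


def test_mean_performing_repeat_selection():
    f1 = np.array([0.6, 0.7, 0.8])  # mean 0.7 -> repeat 1
    assert mean_performing_repeat(f1) == 1
    ties = np.array([0.6, 0.8])  # both equidistant from 0.7 -> earlier
    assert mean_performing_repeat(ties) == 0
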