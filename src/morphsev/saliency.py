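"""Saliency attribution and region-of-interest statistics.

Three attribution routes explain severity predictions:

* **Grad-CAM++** for the 3D CNN: per-channel spatial weights computed from a
  closed form for an exponential-of-score target (alpha = g^2 / (2 g^2 +
  sum A g^3) with g the score gradient on the last convolutional block's
  activations), channel weights sum alpha * ReLU(g), map = ReLU(sum_k w_k
  A_k), trilinearly upsampled to the input grid.
* **Deep SHAP** for the CNN: DeepLIFT rescale multipliers propagated through
  the network against a background set, with an exact max-pool attribution
  rule, so attributions satisfy completeness: they sum to score(x) minus the
  mean background score.
* **Kernel SHAP** for any black-box predictor (here the SVM): Shapley-kernel
  weighted regression over Monte-Carlo coalitions, with absent features
  imputed from the k nearest neighbors of the explained sample (k = 10% of
  the dataset by default).

Maps are rectified (negatives zeroed) and normalized to sum to 1 before group
analysis.  ROI statistics compare mean normalized saliency between correctly
predicted severe and nonsevere groups within six masks: lesion, perilesional
shell, extralesional left-hemisphere tissue, and their right-hemisphere
homologs (midline reflections).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import binom

from .cnn import TrainedCNN
from .nnet import LayerIO, Sequential

EPS = 1e-12


@dataclass
class SaliencyMap:
    grid: np.ndarray
    method: str  # "gradcampp" | "deepshap" | "kernelshap"
    subject_id: str = ""
    predicted_class: int | None = None
    normalized: bool = False


# ---------------------------------------------------------------------------
# Grad-CAM++


def gradcampp(
    model: TrainedCNN, volume: np.ndarray, target_class: int,
    subject_id: str = "",
) -> SaliencyMap:
    """Grad-CAM++ map on the input grid for one subject."""
    x = np.asarray(volume, dtype=np.float32)
    if x.ndim == 3:
        x = x[None, None]
    elif x.ndim == 4:
        x = x[None]
    acts, grads = model.net.activation_and_gradient(
        x, model.last_conv_relu_index, np.array([target_class])
    )
    a = acts[0]  # (C, d, h, w)
    g = grads[0]
    g2, g3 = g * g, g * g * g
    denom = 2.0 * g2 + (a * g3).sum(axis=(1, 2, 3), keepdims=True)
    alpha = np.where(np.abs(denom) > EPS, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    w = (alpha * np.maximum(g, 0.0)).sum(axis=(1, 2, 3))  # per channel
    cam = np.maximum((w[:, None, None, None] * a).sum(axis=0), 0.0)
    if cam.max() <= 0:
        import warnings

        warnings.warn("zero-gradient Grad-CAM++ map")
    up = _trilinear_resize(cam, model.input_shape)
    return SaliencyMap(up, "gradcampp", subject_id, target_class)


def _trilinear_resize(grid: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    factors = [t / s for t, s in zip(target_shape, grid.shape)]
    out = ndimage.zoom(grid, factors, order=1, grid_mode=True, mode="nearest")
    assert out.shape == tuple(target_shape)
    return out


# ---------------------------------------------------------------------------
# Deep SHAP (DeepLIFT rescale)


def deep_shap(
    model: TrainedCNN | Sequential,
    volume: np.ndarray,
    background_set: np.ndarray,
    target_class: int | None = None,
    subject_id: str = "",
) -> np.ndarray:
    """Signed input-space attributions vs a background set.

    For each background sample the DeepLIFT rescale multipliers are propagated
    from the target-class logit down to the input; attributions are
    multiplier * (x - background), averaged over the background set.  The sum
    of attributions equals score(x) - mean background score (completeness).
    """
    net = model.net if isinstance(model, TrainedCNN) else model
    x = np.asarray(volume, dtype=np.float32)
    if x.ndim == 3:
        x = x[None, None]
    elif x.ndim == 4:
        x = x[None]
    bg = np.asarray(background_set, dtype=np.float32)
    if bg.ndim == 4:
        bg = bg[:, None]
    out_x, ios_x = net.forward_cached(x)
    if target_class is None:
        target_class = int(np.argmax(out_x[0]))
    total = np.zeros(x.shape, dtype=np.float64)
    for b in bg:
        _, ios_b = net.forward_cached(b[None])
        m = np.zeros_like(out_x)
        m[0, target_class] = 1.0
        for layer, cx, cb in zip(reversed(net.layers), reversed(ios_x), reversed(ios_b)):
            m = layer.deeplift(m, cx, cb)
        total += (m * (x - b[None])).astype(np.float64)
    attr = (total / len(bg))[0, 0]
    return attr


# ---------------------------------------------------------------------------
# Kernel SHAP


def kernel_shap(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    dataset: np.ndarray,
    k_fraction: float = 0.1,
    n_draws: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Shapley-value estimates for one flat sample under a black-box model.

    Coalition values impute absent features from the k nearest neighbors of
    ``x`` in ``dataset`` (conditional-expectation style).  When the number of
    enumerable coalitions is small they are all used (exact); otherwise
    coalitions are Monte-Carlo sampled with Shapley-kernel weights and the
    attributions solved by constrained weighted least squares.
    """
    x = np.asarray(x, dtype=float).ravel()
    data = np.asarray(dataset, dtype=float)
    p = x.size
    k = max(1, int(round(k_fraction * len(data))))
    if k_fraction * len(data) < 1:
        raise ValueError("k_fraction too small for the dataset size")
    d = np.linalg.norm(data - x, axis=1)
    neighbors = data[np.argsort(d, kind="stable")[:k]]

    def value(mask: np.ndarray) -> float:
        """Mean prediction with absent features imputed from each neighbor."""
        comp = neighbors.copy()
        comp[:, mask] = x[mask]
        return float(np.mean(predict_fn(comp)))

    v_empty = value(np.zeros(p, dtype=bool))
    v_full = value(np.ones(p, dtype=bool))

    n_coalitions = 2**p - 2 if p <= 20 else np.inf
    rng = np.random.default_rng(seed)
    if n_coalitions <= n_draws:
        # exact: enumerate every coalition with its analytic kernel weight
        masks = np.zeros((int(n_coalitions), p), dtype=bool)
        for i in range(1, 2**p - 1):
            masks[i - 1] = [(i >> j) & 1 for j in range(p)]
        sizes = masks.sum(axis=1)
        weights = (p - 1) / (binom(p, sizes) * sizes * (p - sizes))
    else:
        # Monte Carlo: the kernel is encoded in the coalition-size sampling
        # distribution, so each sampled coalition enters with unit weight
        if n_draws < 2 * p:
            import warnings

            warnings.warn("few Monte-Carlo draws; kernel SHAP estimates are noisy")
        sizes = np.arange(1, p)
        w_sizes = (p - 1) / (sizes * (p - sizes))
        w_sizes /= w_sizes.sum()
        # paired (antithetic) sampling: each coalition enters with its
        # complement, a standard variance-reduction for kernel SHAP
        half = (n_draws + 1) // 2
        masks = np.zeros((2 * half, p), dtype=bool)
        for i in range(half):
            s = int(rng.choice(sizes, p=w_sizes))
            chosen = rng.choice(p, size=s, replace=False)
            masks[2 * i, chosen] = True
            masks[2 * i + 1] = ~masks[2 * i]
        weights = np.ones(len(masks))
    z = masks.astype(float)
    vals = np.array([value(m) for m in masks])
    # solve for phi with constraint sum(phi) = v_full - v_empty by elimination
    y = vals - v_empty - z[:, -1] * (v_full - v_empty)
    zt = z[:, :-1] - z[:, [-1]]
    sw = np.sqrt(weights)
    phi_head, *_ = np.linalg.lstsq(zt * sw[:, None], y * sw, rcond=None)
    phi_last = (v_full - v_empty) - phi_head.sum()
    return np.append(phi_head, phi_last)


# ---------------------------------------------------------------------------
# normalization and ROIs


def rectify_and_normalize(map_grid: np.ndarray, method: str = "",
                          subject_id: str = "") -> SaliencyMap:
    """Zero negatives, then divide by the total; an all-zero map stays zero."""
    g = np.maximum(np.asarray(map_grid, dtype=float), 0.0)
    total = g.sum()
    if total > 0:
        g = g / total
        normalized = True
    else:
        normalized = False
    return SaliencyMap(g, method, subject_id, normalized=normalized)


@dataclass
class ROIPartition:
    """Six masks: lesion / perilesional / extralesional and their homologs."""

    lesion: np.ndarray
    perilesional: np.ndarray
    extralesional: np.ndarray
    lesion_homolog: np.ndarray
    perilesional_homolog: np.ndarray
    extralesional_homolog: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "lesion": self.lesion,
            "perilesional": self.perilesional,
            "extralesional": self.extralesional,
            "lesion_homolog": self.lesion_homolog,
            "perilesional_homolog": self.perilesional_homolog,
            "extralesional_homolog": self.extralesional_homolog,
        }


def build_rois(
    lesion_mask: np.ndarray,
    brain_mask: np.ndarray,
    dilation_radius: int = 2,
    connectivity: int = 26,
) -> ROIPartition:
    """Left-hemisphere ROI partition plus right-hemisphere homologs.

    perilesional = (lesion dilated by ``dilation_radius``) minus lesion,
    within left-hemisphere brain tissue; extralesional = the rest of the left
    hemisphere's brain.  Homologs are midline reflections (axis 0), clipped
    to the right hemisphere for lesions touching the midline.
    """
    lesion = np.asarray(lesion_mask).astype(bool)
    brain = np.asarray(brain_mask).astype(bool)
    nx = lesion.shape[0]
    left = np.zeros_like(brain)
    left[: nx // 2] = True
    if (lesion & ~left).any():
        raise ValueError("lesion must be confined to the left hemisphere")
    struct = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    if dilation_radius > 0:
        dilated = ndimage.binary_dilation(
            lesion, structure=struct, iterations=dilation_radius
        )
    else:
        dilated = lesion.copy()
    peri = dilated & ~lesion & brain & left
    extra = brain & left & ~lesion & ~peri
    right = ~left

    def homolog(mask: np.ndarray) -> np.ndarray:
        return np.flip(mask, axis=0) & right

    return ROIPartition(
        lesion=lesion,
        perilesional=peri,
        extralesional=extra,
        lesion_homolog=homolog(lesion),
        perilesional_homolog=homolog(peri),
        extralesional_homolog=homolog(extra),
    )


def roi_group_test(
    maps: list[SaliencyMap] | list[np.ndarray],
    rois: list[ROIPartition],
    predicted_groups: np.ndarray,
) -> pd.DataFrame:
    """Two-sample t-tests of per-ROI mean saliency, severe vs nonsevere.

    Intended for correctly predicted subjects only; ``predicted_groups`` is
    the (correct) predicted class per subject (1 severe, 0 nonsevere).  Each
    subject contributes, per ROI, the mean and the sum of its normalized
    saliency within its own subject-specific masks.
    """
    groups = np.asarray(predicted_groups, dtype=int)
    if min((groups == 0).sum(), (groups == 1).sum()) < 2:
        raise ValueError("each group needs at least 2 subjects")
    grids = [m.grid if isinstance(m, SaliencyMap) else np.asarray(m) for m in maps]
    roi_names = list(rois[0].as_dict().keys())
    per_subject = {name: {"mean": [], "sum": []} for name in roi_names}
    for g, roi in zip(grids, rois):
        for name, mask in roi.as_dict().items():
            vals = g[mask]
            per_subject[name]["mean"].append(vals.mean() if vals.size else 0.0)
            per_subject[name]["sum"].append(vals.sum())
    rows = []
    for name in roi_names:
        means = np.asarray(per_subject[name]["mean"])
        sums = np.asarray(per_subject[name]["sum"])
        a, b = means[groups == 1], means[groups == 0]
        if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "roi": name,
                "mean_severe": float(a.mean()),
                "mean_nonsevere": float(b.mean()),
                "sum_severe": float(sums[groups == 1].mean()),
                "sum_nonsevere": float(sums[groups == 0].mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def mean_performing_repeat(f1_per_repeat: np.ndarray) -> int:
    """Repeat whose F1 is closest to the across-repeat mean; ties earlier."""
    f1 = np.asarray(f1_per_repeat, dtype=float)
    return int(np.argmin(np.abs(f1 - f1.mean())))
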