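"""Class-weighted support vector classification on flat feature tables.

Works interchangeably on flattened scaled volumes, CNN penultimate features,
or flattened saliency maps.  Kernels are linear and radial basis; the RBF
width is parameterized as a *kernel scale* s with K(x, y) =
exp(-||x - y||^2 / s^2) (gamma = 1 / s^2).  Per-class misclassification cost
is multiplied by inverse class frequencies.  Optional PCA or PCA-then-ICA
reduction is fitted on training rows only and tuned (1-75 components) inside
cross-validation.  Hyperparameters are tuned by random search over 300
logarithmically spaced bins per parameter, scored by mean inner-fold weighted
hinge loss.  Probabilities come from a Platt-style sigmoid calibrated on
training-fold decision values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.decomposition import PCA, FastICA
from sklearn.svm import SVC

COST_RANGE = (1e-3, 2e4)
KERNEL_SCALE_RANGE = (1e-3, 1e3)
N_BINS = 300
COMPONENT_RANGE = (1, 75)


@dataclass
class SVMConfig:
    kernel: str = "linear"  # "linear" | "rbf"
    cost: float = 1.0
    kernel_scale: float = 1.0
    reduction: str = "none"  # "none" | "pca" | "ica"
    n_components: int = 10
    n_search_draws: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.reduction not in ("none", "pca", "ica"):
            raise ValueError(f"unsupported reduction {self.reduction!r}")


# ---------------------------------------------------------------------------
# flat tables


def flatten(volumes: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """One row per subject, one column per voxel, C-order voxel indexing.

    The recorded coordinate of column j in a (D, H, W) grid is
    ``np.unravel_index(j, (D, H, W))``.
    """
    arr = np.asarray(volumes, dtype=np.float64)
    if arr.ndim != 4:
        raise ValueError("expected a stack of 3D volumes with one shared grid")
    return arr.reshape(arr.shape[0], -1)


def unflatten(table: np.ndarray, grid_shape: tuple[int, int, int]) -> np.ndarray:
    return np.asarray(table).reshape(-1, *grid_shape)


# ---------------------------------------------------------------------------
# dimensionality reduction (train-only statistics)


@dataclass
class Projector:
    """Maps tables into a k-dim space using training statistics only."""

    method: str
    mean_: np.ndarray
    pca_: PCA
    ica_: FastICA | None = None

    def transform(self, table: np.ndarray) -> np.ndarray:
        z = self.pca_.transform(np.asarray(table, dtype=np.float64))
        if self.ica_ is not None:
            z = self.ica_.transform(z)
        return z


def fit_reduction(
    train_table: np.ndarray, method: str, k: int, seed: int = 0
) -> Projector:
    """PCA, or ICA applied to the top-k principal components ("pca-then-ica")."""
    train_table = np.asarray(train_table, dtype=np.float64)
    n, p = train_table.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n_train-1, n_features)={min(n - 1, p)}")
    pca = PCA(n_components=k, svd_solver="auto", random_state=seed)
    z = pca.fit_transform(train_table)
    ica = None
    if method == "ica":
        ica = FastICA(
            n_components=k, random_state=seed, whiten="unit-variance", max_iter=1000
        )
        ica.fit(z)
    elif method != "pca":
        raise ValueError(f"unknown reduction {method!r}")
    return Projector(method, pca.mean_.copy(), pca, ica)


# ---------------------------------------------------------------------------
# model


@dataclass
class TrainedSVM:
    config: SVMConfig
    svc: SVC
    platt: tuple[float, float]  # (a, b): p_severe = expit(a * f + b)
    projector: Projector | None = None
    degenerate_rate: float | None = None  # fallback constant severe rate

    def _project(self, table: np.ndarray) -> np.ndarray:
        table = np.asarray(table, dtype=np.float64)
        return self.projector.transform(table) if self.projector is not None else table

    def decision_values(self, table: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._project(table))

    def predict(self, table: np.ndarray) -> np.ndarray:
        return (self.decision_values(table) > 0).astype(int)


def _gamma(config: SVMConfig) -> float | str:
    if config.kernel == "rbf":
        return 1.0 / (config.kernel_scale**2)
    return "scale"


def train_svm(
    table: np.ndarray, labels: np.ndarray, config: SVMConfig
) -> TrainedSVM:
    """Fit a class-weighted SVC (SMO) plus Platt calibration, with optional
    train-only dimensionality reduction."""
    table = np.asarray(table, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("two classes required")
    projector = None
    if config.reduction != "none":
        projector = fit_reduction(
            table, config.reduction, config.n_components, config.seed
        )
        table = projector.transform(table)
    counts = np.bincount(labels, minlength=2)
    class_weight = {c: len(labels) / (2.0 * counts[c]) for c in (0, 1)}
    svc = SVC(
        kernel=config.kernel,
        C=config.cost,
        gamma=_gamma(config),
        class_weight=class_weight,
        max_iter=200_000,
        random_state=config.seed,
    )
    svc.fit(table, labels)
    f = svc.decision_function(table)
    a, b = _fit_platt(f, labels)
    return TrainedSVM(config, svc, (a, b), projector)


def _fit_platt(decision: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid on training decision values with regularized targets.

    Monotone nondecreasing in the decision value by construction (a >= 0).
    """
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    t = np.where(labels == 1, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))

    def nll(theta):
        a, b = theta
        p = expit(a * decision + b)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(t * np.log(p) + (1 - t) * np.log(1 - p))

    res = minimize(
        nll, x0=np.array([1.0, 0.0]), method="L-BFGS-B",
        bounds=[(0.0, None), (None, None)],
    )
    return float(res.x[0]), float(res.x[1])


def predict_proba_svm(model: TrainedSVM, table: np.ndarray) -> np.ndarray:
    """Two-column probabilities (nonsevere, severe) from the calibrated sigmoid."""
    if model.degenerate_rate is not None:
        p1 = np.full(len(np.asarray(table)), model.degenerate_rate)
    else:
        a, b = model.platt
        p1 = expit(a * model.decision_values(table) + b)
    return np.column_stack([1.0 - p1, p1])


# ---------------------------------------------------------------------------
# tuning


def weighted_hinge_loss(
    decision: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> float:
    """Mean inverse-frequency-weighted hinge loss; labels in {0, 1}."""
    y = np.where(np.asarray(labels) == 1, 1.0, -1.0)
    w = np.asarray(class_weights)[np.asarray(labels, dtype=int)]
    margins = np.maximum(0.0, 1.0 - y * decision)
    return float((w * margins).sum() / w.sum())


def log_bins(lo: float, hi: float, n_bins: int = N_BINS) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n_bins)


def sample_configs(
    base: SVMConfig, n_draws: int, rng: np.random.Generator
) -> list[SVMConfig]:
    """Random search draws from the logarithmically binned parameter grids."""
    costs = log_bins(*COST_RANGE)
    scales = log_bins(*KERNEL_SCALE_RANGE)
    out = []
    for _ in range(n_draws):
        cfg = replace(
            base,
            cost=float(rng.choice(costs)),
            kernel_scale=float(rng.choice(scales)),
        )
        if base.reduction != "none":
            cfg = replace(
                cfg,
                n_components=int(rng.integers(COMPONENT_RANGE[0], COMPONENT_RANGE[1] + 1)),
            )
        out.append(cfg)
    return out


def tune_svm(
    table: np.ndarray,
    labels: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    base_config: SVMConfig,
    n_draws: int | None = None,
) -> SVMConfig:
    """Pick the draw minimizing mean inner-fold weighted hinge loss.

    The kernel is never tuned: linear and RBF models are trained and reported
    independently.  Reduction statistics are refitted inside every fold.
    """
    table = np.asarray(table, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(base_config.seed)
    draws = sample_configs(base_config, n_draws or base_config.n_search_draws, rng)
    best_cfg, best_loss = None, np.inf
    for cfg in draws:
        fold_losses = []
        ok = True
        for train_ids, held_ids in inner_folds:
            n_train = len(train_ids)
            c = cfg
            if c.reduction != "none":
                k_max = min(n_train - 1, table.shape[1])
                c = replace(c, n_components=min(c.n_components, k_max))
            try:
                model = train_svm(table[train_ids], labels[train_ids], c)
            except ValueError:
                ok = False
                break
            w = len(train_ids) / (
                2.0 * np.bincount(labels[train_ids], minlength=2).astype(float)
            )
            fold_losses.append(
                weighted_hinge_loss(
                    model.decision_values(table[held_ids]), labels[held_ids], w
                )
            )
        if not ok:
            continue
        mean_loss = float(np.mean(fold_losses))
        if mean_loss < best_loss:
            best_loss, best_cfg = mean_loss, cfg
    if best_cfg is None:
        raise RuntimeError("no tunable configuration succeeded")
    return best_cfg
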