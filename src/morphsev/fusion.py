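"""Combining CNN and SVM predictions.

Three families: (i) weighted averaging of the two models' severe-class
probabilities over a weight sweep (w=1 is CNN only, w=0 SVM only); (ii)
stacking with a regularized two-feature linear discriminant trained on a
stratified random half of each outer test fold and evaluated on the other
half, where the regularizer gamma shrinks the pooled covariance toward its
diagonal, Sigma_g = (1-g) Sigma + g diag(Sigma), over 500 linearly spaced
gamma values in [0, 1]; (iii) chaining — SVMs trained on CNN features or
saliency maps — which simply reuses :mod:`morphsev.svm` on other tables.

Sweeps report per-repeat metrics for every value; the "best" value is an
explicitly optimistic bound (max over the sweep), mirroring how best-case
fused performance is assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evaluation import compute_metrics

WEIGHT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)
GAMMA_GRID = np.linspace(0.0, 1.0, 500)


def weighted_average(
    p_cnn: np.ndarray, p_svm: np.ndarray, w: float
) -> tuple[np.ndarray, np.ndarray]:
    """Blend severe-class probabilities: p = w*p_cnn + (1-w)*p_svm.

    Returns (blended severe probability, hard labels with threshold 0.5,
    severe iff p >= 0.5).  Inputs are aligned per-subject severe-class
    probability vectors.
    """
    p_cnn = np.asarray(p_cnn, dtype=float)
    p_svm = np.asarray(p_svm, dtype=float)
    if p_cnn.shape != p_svm.shape:
        raise ValueError("misaligned probability vectors")
    p = w * p_cnn + (1.0 - w) * p_svm
    return p, (p >= 0.5).astype(int)


@dataclass
class ShrunkLDA:
    """Two-class Gaussian LDA with diagonal covariance shrinkage."""

    gamma: float = 0.0
    means_: np.ndarray | None = None
    cov_: np.ndarray | None = None
    priors_: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ShrunkLDA":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        self.means_ = np.stack([x[y == c].mean(axis=0) for c in (0, 1)])
        n = len(y)
        pooled = np.zeros((x.shape[1], x.shape[1]))
        for c in (0, 1):
            xc = x[y == c] - self.means_[c]
            pooled += xc.T @ xc
        pooled /= max(n - 2, 1)
        self.cov_ = (1.0 - self.gamma) * pooled + self.gamma * np.diag(np.diag(pooled))
        # numerical floor for near-singular pooled covariances
        self.cov_ += 1e-10 * np.eye(x.shape[1])
        self.priors_ = np.bincount(y, minlength=2) / n
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        """delta_1(x) - delta_0(x); positive predicts severe."""
        x = np.asarray(x, dtype=float)
        inv = np.linalg.inv(self.cov_)
        scores = []
        for c in (0, 1):
            mu = self.means_[c]
            scores.append(
                x @ inv @ mu - 0.5 * mu @ inv @ mu + np.log(self.priors_[c] + 1e-300)
            )
        return scores[1] - scores[0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_function(x) > 0).astype(int)


def lda_stack(
    p_cnn: np.ndarray,
    p_svm: np.ndarray,
    labels: np.ndarray,
    gamma: float,
    seed: int = 0,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Half-split stacking on the two-feature input (p_cnn, p_svm).

    A stratified random half trains the shrunk LDA; predictions are returned
    for the held-out half as (held_out_indices, predictions).  If a half-split
    leaves a class empty the split is redrawn with a new seed (bounded).
    """
    x = np.column_stack([p_cnn, p_svm])
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        train_idx, eval_idx = _stratified_half(labels, rng)
        ytr = labels[train_idx]
        if len(np.unique(ytr)) == 2 and len(np.unique(labels[eval_idx])) >= 1:
            lda = ShrunkLDA(gamma).fit(x[train_idx], ytr)
            return eval_idx, lda.predict(x[eval_idx])
    raise RuntimeError("could not draw a half-split with both classes present")


def _stratified_half(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, evl = [], []
    for c in np.unique(labels):
        members = np.where(labels == c)[0]
        members = members[rng.permutation(len(members))]
        half = len(members) // 2
        # odd member goes to the training half
        train.extend(members[: len(members) - half])
        evl.extend(members[len(members) - half :])
    return np.asarray(sorted(train)), np.asarray(sorted(evl))


@dataclass
class FusionResult:
    method: str
    sweep_values: np.ndarray
    metrics_per_value: pd.DataFrame  # columns: repeat, value, f1, ...
    best_value: float
    best_f1: float


def sweep(
    method: str,
    values: Sequence[float],
    evaluate: Callable[[float, int], dict[str, float]],
    n_repeats: int,
) -> FusionResult:
    """Evaluate a fused model over a hyperparameter sweep, per repeat.

    ``evaluate(value, repeat)`` returns a metrics dict.  The best value is the
    argmax of mean F1 over repeats — an optimistic best-case bound.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("values must be nonempty")
    rows = []
    for v in values:
        for r in range(n_repeats):
            m = evaluate(float(v), r)
            rows.append({"value": float(v), "repeat": r, **m})
    df = pd.DataFrame(rows)
    mean_f1 = df.groupby("value")["f1"].mean()
    best_value = float(mean_f1.idxmax())
    return FusionResult(method, values, df, best_value, float(mean_f1.max()))


def weighted_average_sweep(
    p_cnn: np.ndarray,
    p_svm: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> FusionResult:
    """Single-repeat convenience sweep of the probability-average weight."""
    weights = WEIGHT_GRID if weights is None else np.asarray(weights)

    def ev(w: float, _r: int) -> dict[str, float]:
        _, pred = weighted_average(p_cnn, p_svm, w)
        return compute_metrics(labels, pred)

    return sweep("weighted_average", weights, ev, n_repeats=1)
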