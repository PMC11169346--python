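"""The 3D VGG-family severity classifier.

Architecture family: 4-5 blocks of 3x3x3 "same" convolutions with ReLU, each
block followed by 2x2x2 max pooling (ceil mode), terminated by three fully
connected layers whose widths are derived from the last convolutional layer's
channel count C: (2C, C, 2), with batch normalization after the first fully
connected layer and dropout immediately after.  Four frozen complexity levels
span the family (channels 8-128, 1-4 convolutions per block); the tuning grid
crosses complexity with dropout rate {0.6, 0.7, 0.8}, L2 {0.001, 0.01} and
initial learning rate {0.1e-4, 0.8e-4, 1e-4}.

Training minimizes binary cross-entropy weighted by inverse class frequencies,
with an L2 penalty, momentum SGD, and a cosine-annealing learning-rate
schedule with warm restarts (first cycle 50 epochs, cycle length doubling,
floor 1e-10).  Early stopping monitors the validation weighted loss and
restores the best weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nnet import (
    BatchNorm1d,
    Conv3d,
    Dropout,
    Flatten,
    Linear,
    MaxPool3d,
    ReLU,
    SGD,
    Sequential,
    l2_penalty,
    weighted_cross_entropy,
)

#: frozen complexity levels: per block, (n_conv_layers, channels)
COMPLEXITY_LEVELS: dict[int, tuple[tuple[int, int], ...]] = {
    1: ((1, 8), (1, 16), (1, 32), (1, 64)),
    2: ((2, 8), (2, 16), (2, 32), (2, 64)),
    3: ((2, 16), (2, 32), (2, 64), (2, 128), (1, 128)),
    4: ((2, 16), (2, 32), (3, 64), (3, 128), (4, 128)),
}

DROPOUT_GRID = (0.6, 0.7, 0.8)
L2_GRID = (0.001, 0.01)
LR_GRID = (0.1e-4, 0.8e-4, 1e-4)


class InvalidArchitectureError(ValueError):
    pass


@dataclass(frozen=True)
class ArchitectureSpec:
    """CNN family member: block layout plus regularization hyperparameters."""

    blocks: tuple[tuple[int, int], ...]
    dropout_rate: float = 0.6
    l2: float = 0.001
    complexity_level: int | None = None

    @classmethod
    def from_level(
        cls, level: int, dropout_rate: float = 0.6, l2: float = 0.001
    ) -> "ArchitectureSpec":
        return cls(COMPLEXITY_LEVELS[level], dropout_rate, l2, complexity_level=level)

    def __post_init__(self) -> None:
        if not (1 <= len(self.blocks)):
            raise InvalidArchitectureError("need at least one block")
        for n_conv, ch in self.blocks:
            if not (1 <= n_conv <= 4):
                raise InvalidArchitectureError("1-4 convolutions per block")
            if not (8 <= ch <= 128):
                raise InvalidArchitectureError("8-128 channels per layer")

    @property
    def c_last(self) -> int:
        return self.blocks[-1][1]

    @property
    def fc_widths(self) -> tuple[int, int, int]:
        return (2 * self.c_last, self.c_last, 2)


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    epochs: int = 800
    batch_size: int = 128
    scheduler_t0: int = 50
    scheduler_t_mult: int = 2
    lr_floor: float = 1e-10
    momentum: float = 0.9
    early_stopping_patience: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_floor >= self.lr0:
            raise ValueError("lr floor must lie below the initial rate")


@dataclass
class TrainedCNN:
    net: Sequential
    spec: ArchitectureSpec
    input_shape: tuple[int, int, int]
    history: dict[str, list[float]]
    best_epoch: int
    chosen_hyperparams: dict = field(default_factory=dict)

    @property
    def feature_layer_index(self) -> int:
        """Index of the ReLU after the second fully connected layer."""
        return self._feature_idx

    @property
    def last_conv_relu_index(self) -> int:
        return self._last_conv_relu_idx


def inverse_frequency_weights(labels: np.ndarray) -> np.ndarray:
    """Per-class weights w_c = N / (2 n_c); ratio w1/w0 = n0/n1."""
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present")
    return len(labels) / (2.0 * counts)


def scheduled_lr(t_in_cycle: float, cycle_len: int, lr0: float, floor: float = 1e-10) -> float:
    """Cosine annealing within one cycle: lr0 at t=0 down to the floor."""
    if not (0 <= t_in_cycle <= cycle_len):
        raise ValueError("t outside cycle")
    return floor + (lr0 - floor) / 2.0 * (1.0 + math.cos(math.pi * t_in_cycle / cycle_len))


def lr_at_epoch(
    epoch: int, lr0: float, t0: int = 50, t_mult: int = 2, floor: float = 1e-10
) -> float:
    """Warm-restart schedule: cycles of length t0, t0*2, t0*4, ...

    Within a cycle of L epochs the rate anneals from lr0 at the first epoch
    down to the floor at the last epoch (epoch L-1), then restarts.
    """
    cycle_len, start = t0, 0
    while epoch >= start + cycle_len:
        start += cycle_len
        cycle_len *= t_mult
    return scheduled_lr(epoch - start, cycle_len - 1, lr0, floor)


def build_network(
    spec: ArchitectureSpec,
    input_shape: tuple[int, int, int],
    seed: int = 0,
    in_channels: int = 1,
) -> TrainedCNN:
    """Construct an untrained network for the given input grid.

    Raises :class:`InvalidArchitectureError`, naming the offending block, if
    the spatial grid would collapse below one voxel per axis.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    dims = list(input_shape)
    ch = in_channels
    last_conv_relu_idx = -1
    for bi, (n_conv, out_ch) in enumerate(spec.blocks):
        if min(dims) < 1:
            raise InvalidArchitectureError(
                f"spatial size collapsed before block {bi} (dims {dims})"
            )
        for _ in range(n_conv):
            layers.append(Conv3d(ch, out_ch, rng))
            layers.append(ReLU())
            ch = out_ch
        last_conv_relu_idx = len(layers) - 1
        layers.append(MaxPool3d())
        dims = [-(-d // 2) for d in dims]
    flat = ch * int(np.prod(dims))
    w1, w2, w3 = spec.fc_widths
    layers.append(Flatten())
    layers.append(Linear(flat, w1, rng))
    layers.append(BatchNorm1d(w1))
    layers.append(Dropout(spec.dropout_rate))
    layers.append(ReLU())
    layers.append(Linear(w1, w2, rng))
    layers.append(ReLU())
    feature_idx = len(layers) - 1  # activation of FC2: the penultimate features
    layers.append(Linear(w2, w3, rng))
    model = TrainedCNN(
        net=Sequential(layers),
        spec=spec,
        input_shape=tuple(input_shape),
        history={"train_loss": [], "val_loss": []},
        best_epoch=-1,
    )
    model._feature_idx = feature_idx
    model._last_conv_relu_idx = last_conv_relu_idx
    return model


class TrainingDivergedError(RuntimeError):
    pass


def train_cnn(
    model: TrainedCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
) -> TrainedCNN:
    """Fit with weighted cross-entropy + L2, scheduled momentum SGD.

    If the training set is smaller than the batch size a single full batch is
    used per epoch.  The weights achieving the best validation weighted loss
    are restored at the end.  NaN loss aborts with a diagnostic.
    """
    rng = np.random.default_rng(config.seed)
    net = model.net
    opt = SGD(net, momentum=config.momentum)
    weights = inverse_frequency_weights(y_train)
    n = len(y_train)
    batch = min(config.batch_size, n)
    best_val = np.inf
    best_state = net.state_copy()
    best_epoch = -1
    since_best = 0
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    for epoch in range(config.epochs):
        lr = lr_at_epoch(
            epoch, config.lr0, config.scheduler_t0, config.scheduler_t_mult,
            config.lr_floor,
        )
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            logits = net.forward(x_train[idx], train=True, rng=rng)
            loss, dlogits = weighted_cross_entropy(logits, y_train[idx], weights)
            loss += l2_penalty(net, model.spec.l2)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={lr:.3g})"
                )
            net.backward(dlogits)
            opt.step(lr, model.spec.l2)
            epoch_loss += loss
            n_batches += 1
        val_loss = evaluate_loss(net, x_val, y_val, weights)
        model.history["train_loss"].append(epoch_loss / n_batches)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = net.state_copy()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    net.load_state(best_state)
    model.best_epoch = best_epoch
    return model


def evaluate_loss(
    net: Sequential, x: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> float:
    logits = net.forward(np.asarray(x, dtype=np.float32), train=False)
    loss, _ = weighted_cross_entropy(logits, y, class_weights)
    return loss


def predict_proba(model: TrainedCNN, volumes: np.ndarray) -> np.ndarray:
    """Softmax class probabilities, one row per subject (rows sum to 1)."""
    x = np.asarray(volumes, dtype=np.float32)
    if x.ndim == 4:
        x = x[:, None]
    logits = model.net.forward(x, train=False)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def extract_features(model: TrainedCNN, volumes: np.ndarray) -> np.ndarray:
    """Penultimate representation: activation of FC2, width C_last."""
    x = np.asarray(volumes, dtype=np.float32)
    if x.ndim == 4:
        x = x[:, None]
    a = x
    for layer in model.net.layers[: model.feature_layer_index + 1]:
        a = layer.forward(a, False, None)
    return a


def default_grid() -> list[ArchitectureSpec]:
    """The full tuning grid: complexity x dropout x L2 (lr handled separately)."""
    return [
        ArchitectureSpec.from_level(level, dr, l2)
        for level in COMPLEXITY_LEVELS
        for dr in DROPOUT_GRID
        for l2 in L2_GRID
    ]


def select_best(
    candidate_losses: dict[tuple, list[float]],
    complexity_of: dict[tuple, int] | None = None,
    lr_of: dict[tuple, float] | None = None,
) -> tuple:
    """Argmin of mean inner-fold loss; ties to lower complexity then lower lr."""
    if not candidate_losses:
        raise ValueError("empty candidate set")
    means = {k: float(np.mean(v)) for k, v in candidate_losses.items()}
    def key(k):
        return (
            means[k],
            (complexity_of or {}).get(k, 0),
            (lr_of or {}).get(k, 0.0),
        )
    return min(means, key=key)


def tune_cnn(
    x: np.ndarray,
    y: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    candidates: list[tuple[ArchitectureSpec, TrainConfig]],
    input_shape: tuple[int, int, int],
) -> tuple[ArchitectureSpec, TrainConfig]:
    """Grid search by smallest mean validation loss over inner folds."""
    losses: dict[int, list[float]] = {i: [] for i in range(len(candidates))}
    for train_ids, held_ids in inner_folds:
        for ci, (spec, tcfg) in enumerate(candidates):
            model = build_network(spec, input_shape, seed=tcfg.seed)
            w = inverse_frequency_weights(y[train_ids])
            train_cnn(
                model, x[train_ids], y[train_ids], x[held_ids], y[held_ids], tcfg
            )
            losses[ci].append(evaluate_loss(model.net, x[held_ids], y[held_ids], w))
    best = select_best(
        {i: v for i, v in losses.items()},
        complexity_of={
            i: (c[0].complexity_level or len(c[0].blocks))
            for i, c in enumerate(candidates)
        },
        lr_of={i: c[1].lr0 for i, c in enumerate(candidates)},
    )
    return candidates[best]
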