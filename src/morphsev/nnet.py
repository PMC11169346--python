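"""Minimal 3D convolutional network engine with explicit backpropagation.

Implements exactly the layer set the severity classifier needs — 3x3x3 "same"
convolutions, ReLU, 2x2x2 max pooling with ceil mode, flatten, fully connected
layers, batch normalization, dropout — plus a momentum SGD optimizer and the
class-weighted cross-entropy loss.  Tensors are float32 arrays shaped
(N, C, D, H, W).

Besides gradients, every layer exposes a DeepLIFT-style multiplier rule
(``deeplift``) used by the Deep SHAP attribution in :mod:`morphsev.saliency`:
multipliers m satisfy sum_i m_i * (x_i - b_i) = f(x) - f(b) layerwise (the
rescale rule; max pooling uses an exact per-window attribution of the change
in the maximum), so completeness holds end to end up to float precision.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

EPS = 1e-12


class Layer:
    """Base layer: forward caches what backward needs; params/grads are dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def deeplift(self, m: np.ndarray, cx: "LayerIO", cb: "LayerIO") -> np.ndarray:
        """Propagate multipliers from output to input (rescale framework)."""
        raise NotImplementedError

    @property
    def weight_keys(self) -> tuple[str, ...]:
        """Parameter names subject to the L2 penalty (weights, not biases)."""
        return ()


class LayerIO:
    """Input/output snapshot of one layer during a cached forward pass."""

    __slots__ = ("x", "y", "extra")

    def __init__(self, x: np.ndarray, y: np.ndarray, extra=None):
        self.x, self.y, self.extra = x, y, extra


_OFFSETS = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]


class Conv3d(Layer):
    """3x3x3 convolution with "same" zero padding (stride 1)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * 27
        self.params["W"] = (
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, 3, 3, 3))
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.in_ch, self.out_ch = in_ch, out_ch

    @property
    def weight_keys(self) -> tuple[str, ...]:
        return ("W",)

    def _conv(self, x: np.ndarray, W: np.ndarray, b: np.ndarray | None) -> np.ndarray:
        N, C, D, H, Wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        out = np.zeros((N, D, H, Wd, W.shape[0]), dtype=np.float32)
        for (a, bb, c) in _OFFSETS:
            view = xp[:, :, a : a + D, bb : bb + H, c : c + Wd]
            # (N,C,D,H,W) x (O,C) -> (N,D,H,W,O)
            out += np.tensordot(view, W[:, :, a, bb, c], axes=([1], [1]))
        if b is not None:
            out += b
        return np.ascontiguousarray(np.moveaxis(out, -1, 1))

    def forward(self, x, train, rng):
        self._x = x
        return self._conv(x, self.params["W"], self.params["b"])

    def backward(self, dout):
        x = self._x
        N, C, D, H, Wd = x.shape
        W = self.params["W"]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(W)
        do = np.moveaxis(dout, 1, -1)  # (N,D,H,W,O)
        for (a, bb, c) in _OFFSETS:
            view = xp[:, :, a : a + D, bb : bb + H, c : c + Wd]
            # dW: sum over N and space
            dW[:, :, a, bb, c] = np.tensordot(
                do, view, axes=([0, 1, 2, 3], [0, 2, 3, 4])
            )
            # dX: (N,D,H,W,O) x (O,C) -> (N,D,H,W,C)
            dview = np.tensordot(do, W[:, :, a, bb, c], axes=([4], [0]))
            dxp[:, :, a : a + D, bb : bb + H, c : c + Wd] += np.moveaxis(dview, -1, 1)
        self.grads["W"] = dW
        self.grads["b"] = do.sum(axis=(0, 1, 2, 3))
        return dxp[:, :, 1:-1, 1:-1, 1:-1]

    def deeplift(self, m, cx, cb):
        # affine layer: multipliers propagate exactly like gradients
        self._x = cx.x
        saved_grads = dict(self.grads)
        dm = self.backward(m)
        self.grads = saved_grads
        return dm


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return dout * self._mask

    def deeplift(self, m, cx, cb):
        dx = cx.x - cb.x
        dy = cx.y - cb.y
        ratio = np.where(np.abs(dx) > 1e-7, dy / np.where(dx == 0, 1.0, dx), (cx.x > 0))
        return m * ratio.astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 and ceil mode (odd edges padded)."""

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        N, C, D, H, W = x.shape
        D2, H2, W2 = -(-D // 2), -(-H // 2), -(-W // 2)
        xp = np.full((N, C, D2 * 2, H2 * 2, W2 * 2), -np.inf, dtype=np.float32)
        xp[:, :, :D, :H, :W] = x
        windows = xp.reshape(N, C, D2, 2, H2, 2, W2, 2)
        flat = windows.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, D2, H2, W2, 8)
        self._arg = np.argmax(flat, axis=-1)
        self._flat_shape = flat.shape
        return np.max(flat, axis=-1)

    def backward(self, dout):
        N, C, D2, H2, W2, _ = self._flat_shape
        dflat = np.zeros(self._flat_shape, dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        return self._unflatten(dflat)

    def _unflatten(self, dflat):
        N, C, D2, H2, W2, _ = self._flat_shape
        dxp = (
            dflat.reshape(N, C, D2, H2, W2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(N, C, D2 * 2, H2 * 2, W2 * 2)
        )
        _, _, D, H, W = self._in_shape
        return dxp[:, :, :D, :H, :W]

    def _window_flat(self, x):
        N, C, D, H, W = x.shape
        D2, H2, W2 = -(-D // 2), -(-H // 2), -(-W // 2)
        xp = np.full((N, C, D2 * 2, H2 * 2, W2 * 2), -np.inf, dtype=np.float32)
        xp[:, :, :D, :H, :W] = x
        w = xp.reshape(N, C, D2, 2, H2, 2, W2, 2)
        return w.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(N, C, D2, H2, W2, 8)

    def deeplift(self, m, cx, cb):
        """Exact rule: the change in each window's max is attributed to one
        input whose own change carries it, preserving completeness."""
        fx = self._window_flat(cx.x)
        fb = self._window_flat(cb.x)
        dy = np.max(fx, axis=-1) - np.max(fb, axis=-1)  # (N,C,D2,H2,W2)
        dxs = np.where(np.isfinite(fx), fx, 0.0) - np.where(np.isfinite(fb), fb, 0.0)
        argx = np.argmax(fx, axis=-1)
        d_at_argx = np.take_along_axis(dxs, argx[..., None], axis=-1)[..., 0]
        arg_best = np.argmax(np.abs(dxs), axis=-1)
        use_argx = np.abs(d_at_argx) > 1e-9
        chosen = np.where(use_argx, argx, arg_best)
        d_chosen = np.take_along_axis(dxs, chosen[..., None], axis=-1)[..., 0]
        mult = np.where(np.abs(d_chosen) > 1e-12, dy / np.where(d_chosen == 0, 1.0, d_chosen), 0.0)
        mflat = np.zeros(fx.shape, dtype=np.float32)
        np.put_along_axis(mflat, chosen[..., None], (m * mult)[..., None], axis=-1)
        self._in_shape = cx.x.shape
        self._flat_shape = fx.shape
        return self._unflatten(mflat)


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def deeplift(self, m, cx, cb):
        return m.reshape(cx.x.shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)
        ).astype(np.float32)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    @property
    def weight_keys(self) -> tuple[str, ...]:
        return ("W",)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]

    def deeplift(self, m, cx, cb):
        return m @ self.params["W"]


class BatchNorm1d(Layer):
    """Batch normalization over feature columns of a (N, F) tensor."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(n_features, dtype=np.float32)
        self.params["beta"] = np.zeros(n_features, dtype=np.float32)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train, rng):
        if train and x.shape[0] > 1:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._train_batch = train and x.shape[0] > 1
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        g = self.params["gamma"]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=0)
        self.grads["beta"] = dout.sum(axis=0)
        if not self._train_batch:
            return dout * g / self._std
        N = dout.shape[0]
        dxhat = dout * g
        return (
            dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std

    def deeplift(self, m, cx, cb):
        # eval-mode batch norm is affine in its input
        scale = self.params["gamma"] / np.sqrt(self.running_var + self.eps)
        return m * scale


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout rate must be in [0,1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        assert rng is not None, "training-mode dropout needs an rng"
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(np.float32)

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def deeplift(self, m, cx, cb):
        return m  # identity at inference


class GlobalAvgPool3d(Layer):
    """Spatial mean over (D, H, W); used by attribution oracles and tests."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        N, C, D, H, W = self._shape
        return np.broadcast_to(
            dout[:, :, None, None, None] / (D * H * W), self._shape
        ).astype(np.float32)

    def deeplift(self, m, cx, cb):
        self._shape = cx.x.shape
        return self.backward(m)


class Sequential:
    """Ordered layer stack with cached forward and full/partial backward."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Backpropagate to the *output* of layer ``stop_at - 1``.

        With the default stop_at=0 the gradient w.r.t. the network input is
        returned; with stop_at=k the returned array is the gradient w.r.t.
        the input of layer k (= output of layer k-1).
        """
        for layer in reversed(self.layers[stop_at:]):
            dout = layer.backward(dout)
        return dout

    def forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, list[LayerIO]]:
        """Inference-mode forward recording every layer's input and output."""
        ios: list[LayerIO] = []
        for layer in self.layers:
            y = layer.forward(x, False, None)
            ios.append(LayerIO(x, y))
            x = y
        return x, ios

    def activation_and_gradient(
        self, x: np.ndarray, layer_idx: int, target: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Output of layer ``layer_idx`` and d(score)/d(that output).

        ``target`` is an integer class per subject; the score is the target
        class logit.  Inference mode (dropout off, running batch-norm stats).
        """
        a = x
        for layer in self.layers[: layer_idx + 1]:
            a = layer.forward(a, False, None)
        out = a
        for layer in self.layers[layer_idx + 1 :]:
            out = layer.forward(out, False, None)
        seed = np.zeros_like(out)
        seed[np.arange(out.shape[0]), np.asarray(target, dtype=int)] = 1.0
        grad = self.backward(seed, stop_at=layer_idx + 1)
        return a, grad

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                yield (i, k), layer

    def state_copy(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self.layers:
            d = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm1d):
                d["__running_mean"] = layer.running_mean.copy()
                d["__running_var"] = layer.running_var.copy()
            state.append(d)
        return state

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, d in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = d[k].copy()
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = d["__running_mean"].copy()
                layer.running_var = d["__running_var"].copy()


# ---------------------------------------------------------------------------
# loss and optimizer


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy (weighted mean over the batch).

    With weights (1, 1) this equals the plain mean cross-entropy.  Returns the
    loss and its gradient w.r.t. the logits.
    """
    y = np.asarray(y, dtype=int)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    w = np.asarray(class_weights, dtype=np.float64)[y]
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), y], EPS, None))
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad.astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, net: Sequential, momentum: float = 0.9):
        self.net = net
        self.momentum = momentum
        self.velocity: dict[tuple[int, str], np.ndarray] = {}

    def step(self, lr: float, l2: float = 0.0) -> None:
        for i, layer in enumerate(self.net.layers):
            for k, param in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                if l2 > 0 and k in layer.weight_keys:
                    g = g + 2.0 * l2 * param
                v = self.velocity.get((i, k))
                v = g if v is None else self.momentum * v + g
                self.velocity[(i, k)] = v
                layer.params[k] = param - lr * v


def l2_penalty(net: Sequential, l2: float) -> float:
    if l2 == 0:
        return 0.0
    total = 0.0
    for layer in net.layers:
        for k in layer.weight_keys:
            total += float((layer.params[k] ** 2).sum())
    return l2 * total
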