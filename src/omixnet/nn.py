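"""Minimal numpy neural-network engine for the multi-branch CNN.

Implements exactly the layer set the architecture needs — 1-D convolution
along the feature axis, leaky ReLU, global max pooling, batch normalization,
dense layers, inverted dropout — with explicit forward/backward passes and an
Adam optimizer. Backpropagation continues through to the inputs so that
gradient saliency maps come from the same machinery that trains the model.

Shapes: convolutional tensors are (batch, positions, channels); dense
activations are (batch, units).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless unless it declares parameters in ``params``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trained state (BN running stats)

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution along axis 1 (valid padding, stride 1).

    Weight shape (kernel, c_in, c_out); input (N, L, c_in) -> (N, L-k+1, c_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        fan_in = kernel * c_in
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, c_in, c_out))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train, rng):
        # sum over kernel offsets of a plain matmul keeps everything in BLAS
        W = self.params["W"]
        k = self.kernel
        L = x.shape[1] - k + 1
        self._x = x
        out = self.params["b"] + x[:, 0:L, :] @ W[0]
        for j in range(1, k):
            out += x[:, j:j + L, :] @ W[j]
        return out

    def backward(self, gout):
        W = self.params["W"]
        x = self._x
        k = self.kernel
        L = gout.shape[1]
        n, _, c_in = x.shape
        g2 = gout.reshape(n * L, -1)
        dW = np.empty_like(W)
        gin = np.zeros(x.shape)
        for j in range(k):
            dW[j] = x[:, j:j + L, :].reshape(n * L, c_in).T @ g2
            gin[:, j:j + L, :] += gout @ W[j].T
        self.grads["W"] = dW
        self.grads["b"] = gout.sum(axis=(0, 1))
        return gin


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x, train, rng):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, gout):
        return np.where(self._neg, self.slope * gout, gout)


class GlobalMaxPool(Layer):
    """(N, L, C) -> (N, C), taking the max over positions."""

    def forward(self, x, train, rng):
        self._arg = np.argmax(x, axis=1)
        self._in_shape = x.shape
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, gout):
        gin = np.zeros(self._in_shape)
        n, _, c = self._in_shape
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        gin[ni, self._arg, ci] = gout
        return gin


class MaxPool1D(Layer):
    """Non-overlapping max pooling over positions; a short trailing window
    is padded with -inf and never wins."""

    def __init__(self, width: int):
        super().__init__()
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x, train, rng):
        n, L, c = x.shape
        w = min(self.width, L)
        n_win = -(-L // w)
        pad = n_win * w - L
        self._in_shape = x.shape
        self._w, self._n_win = w, n_win
        if pad:
            x = np.concatenate([x, np.full((n, pad, c), -np.inf)], axis=1)
        xw = x.reshape(n, n_win, w, c)
        self._arg = np.argmax(xw, axis=2)  # (n, n_win, c)
        return np.take_along_axis(xw, self._arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, gout):
        n, L, c = self._in_shape
        gin = np.zeros((n, self._n_win * self._w, c))
        gw = gin.reshape(n, self._n_win, self._w, c)
        np.put_along_axis(gw, self._arg[:, :, None, :], gout[:, :, None, :], axis=2)
        return gin[:, :L, :]


class Flatten(Layer):
    """(N, L, C) -> (N, L*C)."""

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._in_shape)


class BatchNorm(Layer):
    """Batch normalization on (N, C) vectors; running stats for inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(dim)
        self.params["beta"] = np.zeros(dim)
        self.state["running_mean"] = np.zeros(dim)
        self.state["running_var"] = np.ones(dim)

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.state["running_mean"] = m * self.state["running_mean"] + (1 - m) * mu
            self.state["running_var"] = m * self.state["running_var"] + (1 - m) * var
        else:
            mu = self.state["running_mean"]
            var = self.state["running_var"]
        self._train = train
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, gout):
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (gout * xhat).sum(axis=0)
        self.grads["beta"] = gout.sum(axis=0)
        g = gout * self.params["gamma"]
        if not self._train:
            return g * istd
        n = gout.shape[0]
        return (istd / n) * (n * g - g.sum(axis=0) - xhat * (g * xhat).sum(axis=0))


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gout):
        self.grads["W"] = self._x.T @ gout
        self.grads["b"] = gout.sum(axis=0)
        return gout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train, rng):
        for lay in self.layers:
            x = lay.forward(x, train, rng)
        return x

    def backward(self, gout):
        for lay in reversed(self.layers):
            gout = lay.backward(gout)
        return gout


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           class_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    w = class_weights[y]
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / w.sum())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


def mse_loss(pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and gradient w.r.t. the (N, 1) prediction."""
    diff = pred[:, 0] - y
    loss = float(np.mean(diff ** 2))
    grad = (2.0 / len(y)) * diff[:, None]
    return loss, grad


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def collect_params(layers: list[Layer]) -> dict[str, np.ndarray]:
    out = {}
    for i, lay in enumerate(layers):
        for k, v in lay.params.items():
            out[f"{i}/{k}"] = v
        for k, v in lay.state.items():
            out[f"{i}/state/{k}"] = v
    return out


def snapshot_params(layers: list[Layer]) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in collect_params(layers).items()}


def restore_params(layers: list[Layer], snap: dict[str, np.ndarray]) -> None:
    for i, lay in enumerate(layers):
        for k in lay.params:
            lay.params[k][...] = snap[f"{i}/{k}"]
        for k in lay.state:
            lay.state[k][...] = snap[f"{i}/state/{k}"]
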