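"""Minimal NumPy neural-network primitives.

Purpose-built layers, losses and optimizers sufficient for the two small
networks in this package (a dense regression net and a 1-D convolutional
classifier).  Everything is deterministic given the RNG passed at
construction, and every optimizer update rule is implemented exactly as its
textbook formula so single steps can be verified by hand.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .exceptions import DivergenceError, ShapeError


class Layer:
    """Base layer: holds parameters and gradients in parallel dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, scale, size=(n_in, n_out))
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class PReLU(Layer):
    """Parametric rectifier with a single learned slope (init 0.25)."""

    def __init__(self, init_slope: float = 0.25) -> None:
        super().__init__()
        self.params["a"] = np.array([init_slope])

    def forward(self, x, train):
        self._x = x
        a = self.params["a"][0]
        return np.where(x > 0, x, a * x)

    def backward(self, grad):
        x = self._x
        self.grads["a"] = np.array([np.sum(grad * np.where(x > 0, 0.0, x))])
        a = self.params["a"][0]
        return grad * np.where(x > 0, 1.0, a)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ShapeError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv1d(Layer):
    """1-D convolution with 'same' padding (odd kernel), stride 1.

    Input/output shape (N, C, L).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ShapeError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params["W"] = rng.normal(0.0, scale, size=(c_out, c_in, kernel))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train):
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,C,L,k)
        self._cols = cols
        out = np.einsum("nclk,ock->nol", cols, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None]

    def backward(self, grad):
        k = self.kernel
        p = k // 2
        W = self.params["W"]
        self.grads["W"] = np.einsum("nclk,nol->ock", self._cols, grad, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2))
        n, _, length = grad.shape
        gxp = np.zeros((n, W.shape[1], length + 2 * p))
        for t in range(k):
            gxp[:, :, t : t + length] += np.einsum(
                "nol,oc->ncl", grad, W[:, :, t], optimize=True
            )
        return gxp[:, :, p : p + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (N, C, L) inputs."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None]
        self._xhat = (x - mean[None, :, None]) / self._std
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][
            None, :, None
        ]

    def backward(self, grad):
        xhat = self._xhat
        self.grads["gamma"] = np.sum(grad * xhat, axis=(0, 2))
        self.grads["beta"] = np.sum(grad, axis=(0, 2))
        g = grad * self.params["gamma"][None, :, None]
        m = grad.shape[0] * grad.shape[2]
        return (
            g - g.mean(axis=(0, 2), keepdims=True) - xhat * (g * xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std


class AvgPool1d(Layer):
    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x, train):
        n, c, length = x.shape
        if length % self.factor != 0:
            raise ShapeError(f"length {length} not divisible by pool factor {self.factor}")
        self._shape = x.shape
        return x.reshape(n, c, length // self.factor, self.factor).mean(axis=3)

    def backward(self, grad):
        return np.repeat(grad, self.factor, axis=2) / self.factor


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> List[Tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def get_weights(self) -> List[np.ndarray]:
        return [layer.params[name] for layer, name in self.parameters()]

    def get_grads(self) -> List[np.ndarray]:
        return [layer.grads[name] for layer, name in self.parameters()]

    def state_dict(self) -> dict:
        state = {}
        for k, (layer, name) in enumerate(self.parameters()):
            state[f"{k}:{type(layer).__name__}:{name}"] = layer.params[name].tolist()
        for k, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                state[f"bn{k}:running_mean"] = layer.running_mean.tolist()
                state[f"bn{k}:running_var"] = layer.running_var.tolist()
        return state

    def load_state_dict(self, state: dict) -> None:
        for k, (layer, name) in enumerate(self.parameters()):
            key = f"{k}:{type(layer).__name__}:{name}"
            layer.params[name] = np.asarray(state[key], dtype=float)
        for k, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.asarray(state[f"bn{k}:running_mean"], dtype=float)
                layer.running_var = np.asarray(state[f"bn{k}:running_var"], dtype=float)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def mse_value_and_grad(pred: np.ndarray, true: np.ndarray) -> Tuple[float, np.ndarray]:
    if pred.shape != true.shape:
        raise ShapeError(f"shape mismatch {pred.shape} vs {true.shape}")
    diff = pred - true
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean cross entropy over integer labels; returns (loss, grad wrt logits)."""
    n = logits.shape[0]
    probs = softmax(logits)
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class AdagradOptimizer:
    """theta <- theta - eta * g / sqrt(G + eps), G accumulating g^2."""

    def __init__(self, net: Sequential, lr: float = 0.01, eps: float = 1e-8) -> None:
        self.net = net
        self.lr = lr
        self.eps = eps
        self.accum = [np.zeros_like(p) for p in net.get_weights()]

    def step(self) -> None:
        for acc, (layer, name) in zip(self.accum, self.net.parameters()):
            g = layer.grads[name]
            if not np.all(np.isfinite(g)):
                raise DivergenceError(f"non-finite gradient in {type(layer).__name__}.{name}")
            acc += g * g
            layer.params[name] = layer.params[name] - self.lr * g / np.sqrt(acc + self.eps)


class AdamOptimizer:
    """Adam with bias correction, exactly the standard update."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in net.get_weights()]
        self.v = [np.zeros_like(p) for p in net.get_weights()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for m, v, (layer, name) in zip(self.m, self.v, self.net.parameters()):
            g = layer.grads[name]
            if not np.all(np.isfinite(g)):
                raise DivergenceError(f"non-finite gradient in {type(layer).__name__}.{name}")
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            layer.params[name] = layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
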