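"""A small deterministic 1-D convolutional network engine.

Implements exactly the pieces the spindle detector needs -- same-padding 1-D
convolution, floor-mode max pooling, ReLU, fully connected layers, softmax
cross-entropy and Adam -- in plain numpy, so that single-thread CPU training
is bit-reproducible under a fixed seed. Backward passes are exercised against
numerical gradients in the test suite.

Shapes: batches are ``(B, C, L)`` for convolutional layers and ``(B, D)``
after flattening.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "MaxPool1d",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(B, C, Lp) -> (B*Lout, C*k) with Lout = Lp - k + 1."""
    b, c, _ = xp.shape
    view = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B, C, Lout, k)
    lout = view.shape[2]
    return view.transpose(0, 2, 1, 3).reshape(b * lout, c * k), lout


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv1d(Layer):
    """Same-padding, stride-1 cross-correlation."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        fan_in = in_channels * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel))
        self.b = np.zeros(out_channels)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.pl = (kernel - 1) // 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        pr = self.k - 1 - self.pl
        xp = np.pad(x, ((0, 0), (0, 0), (self.pl, pr)))
        cols, lout = _im2col(xp, self.k)
        self._cols, self._lshape = cols, (b, l)
        y = cols @ self.w.reshape(self.cout, -1).T + self.b
        return y.reshape(b, lout, self.cout).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, l = self._lshape
        dymat = dy.transpose(0, 2, 1).reshape(b * l, self.cout)
        self.dw = (dymat.T @ self._cols).reshape(self.w.shape)
        self.db = dy.sum(axis=(0, 2))
        # dx = correlation of padded dy with the flipped, transposed kernel
        wflip = self.w[:, :, ::-1].transpose(1, 0, 2)           # (C, F, K)
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.k - 1 - self.pl, self.pl)))
        cols, lout = _im2col(dyp, self.k)
        dx = cols @ wflip.reshape(self.cin, -1).T
        return dx.reshape(b, lout, self.cin).transpose(0, 2, 1)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class MaxPool1d(Layer):
    """Floor-mode max pooling: trailing samples that do not fill a bin are dropped."""

    def __init__(self, factor: int):
        self.p = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, l = x.shape
        lout = l // self.p
        xr = x[:, :, : lout * self.p].reshape(b, c, lout, self.p)
        self._arg = xr.argmax(axis=3)
        self._inshape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, lout = dy.shape
        dxr = np.zeros((b, c, lout, self.p))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._inshape)
        dx[:, :, : lout * self.p] = dxr.reshape(b, c, lout * self.p)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.w

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state):
            p[...] = s


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient with respect to the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
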