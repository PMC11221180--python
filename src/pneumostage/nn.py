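"""Minimal CPU neural-network engine.

A compact layer library (2-D convolution, pooling, nearest-neighbour
upsampling, dense heads) with hand-written backpropagation and an Adam
optimizer, sized for desk-scale experiments on phantom radiographs.
Tensors are NCHW ``float32``; every layer caches what its backward pass
needs, so ``forward`` must precede ``backward`` within a step.

Weight initialisation is He-normal drawn from a caller-supplied
``numpy.random.Generator`` — two models built with the same generator
state are bit-identical, which the pipeline's determinism contract
relies on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "Dense",
    "ResidualBlock",
    "Sequential",
    "Adam",
    "sigmoid",
    "softmax",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base class: parameters live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return [self]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> column tensor (N,Ho,Wo,C*k*k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n, c, ho, wo, _, _ = win.shape
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n, ho, wo, c * k * k), x.shape


class Conv2D(Layer):
    """k×k convolution, 'same'-style symmetric zero padding by default."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        self.params["W"] = (rng.standard_normal((cout, cin * k * k)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, self._xshape_padded = _im2col(x, self.k, self.stride, self.pad)
        self._cols = cols
        self._xshape = x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(out.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, ho, wo = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        dyf2 = dyf.reshape(-1, self.cout)
        self.grads["W"] = (dyf2.T @ cols2).astype(np.float32)
        self.grads["b"] = dyf2.sum(axis=0).astype(np.float32)
        dcols = (dyf2 @ self.params["W"]).reshape(n, ho, wo, self.cin, self.k, self.k)
        _, c, hp, wp = self._xshape_padded
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; ties resolved to the first occurrence."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = win.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dy.shape
        flat = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return flat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(self._inshape).astype(np.float32)


class Upsample2(Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        return (np.broadcast_to(dy[:, :, None, None], self._inshape) / (h * w)).astype(np.float32)


class GlobalMaxPool(Layer):
    """Channel-wise spatial max; suited to 'feature present anywhere' heads."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._idx = flat.argmax(axis=2)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=2)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        flat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=2)
        return flat.reshape(self._inshape)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.params["W"] = (rng.standard_normal((cout, cin)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (dy.T @ self._x).astype(np.float32)
        self.grads["b"] = dy.sum(axis=0).astype(np.float32)
        return (dy @ self.params["W"]).astype(np.float32)


class ResidualBlock(Layer):
    """conv–ReLU–conv plus identity (or 1×1 projection) shortcut, ReLU after the sum."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv2D(cin, cout, 3, stride=stride, rng=rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(cout, cout, 3, rng=rng)
        self.proj = Conv2D(cin, cout, 1, stride=stride, pad=0, rng=rng) if (stride != 1 or cin != cout) else None
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(h + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        if self.proj is not None:
            dx = dx + self.proj.backward(d)
        else:
            dx = dx + d
        return dx

    def sublayers(self) -> list[Layer]:
        out = [self.conv1, self.conv2]
        if self.proj is not None:
            out.append(self.proj)
        return out


class Sequential:
    """Plain layer chain with chained backward; parameters via ``layers``."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def param_layers(self) -> list[Layer]:
        out = []
        for lay in self.layers:
            out.extend(s for s in lay.sublayers() if s.params)
        return out

    def state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in lay.params.items()} for lay in self.param_layers()]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for lay, st in zip(self.param_layers(), state):
            for k in lay.params:
                lay.params[k][...] = st[k]


class Adam:
    """Adam with optional stepped learning-rate decay (×factor every ``decay_every`` epochs)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 decay_factor: float = 1.0, decay_every: int | None = None):
        self.layers = [l for l in layers if l.params]
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.decay_factor = decay_factor
        self.decay_every = decay_every
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in self.layers]

    def current_lr(self, epoch: int = 0) -> float:
        if self.decay_every:
            return self.lr0 * self.decay_factor ** (epoch // self.decay_every)
        return self.lr0

    def step(self, epoch: int = 0) -> None:
        self.t += 1
        lr = self.current_lr(epoch)
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mh = m[k] / (1 - self.b1 ** self.t)
                vh = v[k] / (1 - self.b2 ** self.t)
                p -= (lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)
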