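"""Minimal NumPy neural-network layers with hand-written backprop.

Only the pieces the part-prototype architecture needs: strided 2-D
convolution (im2col), ReLU, sigmoid, linear, and global average pooling.
All arrays are float32, NCHW layout. Each layer caches what its backward
pass needs; `backward` consumes the upstream gradient and accumulates
parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (B,C,H,W) into (B, C*k*k, L) patch columns."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(cols).reshape(b, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((b, c, hp, wp), dtype=DTYPE)
    d6 = dcols.reshape(b, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d6[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


class Layer:
    """Base class; parameter-free layers leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self) -> None:
        for name, p in self.params.items():
            self.grads[name] = np.zeros_like(p)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.pad = stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k * k
        # He initialization: suits the ReLU nonlinearities downstream
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.params = {"W": w.astype(DTYPE), "b": np.zeros(out_ch, dtype=DTYPE)}
        self.zero_grad()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        out = np.einsum("of,bfl->bol", wmat, cols, optimize=True)
        out += self.params["b"][None, :, None]
        self._cache = (x.shape, cols, ho, wo)
        return out.reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, cols, ho, wo = self._cache
        b = dout.shape[0]
        dmat = dout.reshape(b, self.out_ch, ho * wo)
        wmat = self.params["W"].reshape(self.out_ch, -1)
        self.grads["W"] += np.einsum("bol,bfl->of", dmat, cols,
                                     optimize=True).reshape(self.params["W"].shape)
        self.grads["b"] += dmat.sum(axis=(0, 2))
        dcols = np.einsum("of,bol->bfl", wmat, dmat, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0).astype(DTYPE)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # numerically-stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._out * (1.0 - self._out)).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.params = {"W": w.astype(DTYPE), "b": np.zeros(out_dim, dtype=DTYPE)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return (dout @ self.params["W"]).astype(DTYPE)


class GlobalAvgPool(Layer):
    """(B,C,H,W) -> (B,C) mean over the spatial grid."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)).astype(DTYPE)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self):
        """Yield (key, param, grad_dict, name) handles for the optimizer."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}.{name}", layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": layer.params[name].copy()
                for i, layer in enumerate(self.layers) for name in layer.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].astype(DTYPE).copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean CE over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(np.float64).tiny
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)
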