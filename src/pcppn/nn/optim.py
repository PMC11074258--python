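"""Adam optimizer for the NumPy layer stack."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam (Kingma & Ba) over a list of (key, layer, name) handles."""

    def __init__(self, handles, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.handles = list(handles)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {key: np.zeros_like(layer.params[name], dtype=np.float64)
                  for key, layer, name in self.handles}
        self.v = {key: np.zeros_like(layer.params[name], dtype=np.float64)
                  for key, layer, name in self.handles}

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for key, layer, name in self.handles:
            g = layer.grads[name]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / bc1
            vhat = self.v[key] / bc2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype)

    def zero_grad(self) -> None:
        seen = set()
        for _, layer, _ in self.handles:
            if id(layer) not in seen:
                layer.zero_grad()
                seen.add(id(layer))


class ArrayAdam:
    """Adam on a bare ndarray (used for the prototype matrix)."""

    def __init__(self, shape, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = np.zeros(shape, dtype=np.float64)
        self.v = np.zeros(shape, dtype=np.float64)

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mhat = self.m / (1.0 - self.b1 ** self.t)
        vhat = self.v / (1.0 - self.b2 ** self.t)
        param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(param.dtype)
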