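"""Small convolutional backbones.

The default ``tiny`` backbone is a 3-block strided CNN with total stride 16
(a 64x64 input yields a 4x4 patch grid), sized so that the whole
part-prototype pipeline trains on a single CPU core in minutes. Backbones
are registered by name so the choice is configuration, not a code fork.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, GlobalAvgPool, Linear, ReLU, Sequential, cross_entropy

#: name -> (block spec list of (out_ch, kernel, stride, pad), output channels)
BACKBONES = {
    # 5x5/s4 then two 3x3/s2: total stride 16, receptive field 29 px
    "tiny": [(16, 5, 4, 2), (32, 3, 2, 1), (64, 3, 2, 1)],
    # slightly wider variant, same geometry (used for reproducibility probes)
    "tiny_wide": [(24, 5, 4, 2), (48, 3, 2, 1), (96, 3, 2, 1)],
    # deeper 4-block / stride 16 variant
    "tiny_deep": [(16, 3, 2, 1), (32, 3, 2, 1), (64, 3, 2, 1), (64, 3, 2, 1)],
}


def backbone_stride(name: str) -> int:
    return int(np.prod([s for _, _, s, _ in BACKBONES[name]]))


def backbone_channels(name: str) -> int:
    return BACKBONES[name][-1][0]


def build_backbone(name: str, rng: np.random.Generator) -> Sequential:
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; known: {sorted(BACKBONES)}")
    layers = []
    in_ch = 3
    for out_ch, k, stride, pad in BACKBONES[name]:
        layers.append(Conv2d(in_ch, out_ch, k, stride=stride, pad=pad, rng=rng))
        layers.append(ReLU())
        in_ch = out_ch
    return Sequential(layers)


class ConvClassifier:
    """Backbone + global average pool + linear softmax classifier.

    Serves as the black-box model whose penultimate (pooled) activations form
    the latent space used for per-class clustering.
    """

    def __init__(self, backbone_name: str, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.backbone_name = backbone_name
        self.n_classes = n_classes
        self.features = build_backbone(backbone_name, rng)
        self.pool = GlobalAvgPool()
        self.head = Linear(backbone_channels(backbone_name), n_classes, rng=rng)
        self.embedding_dim = backbone_channels(backbone_name)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Penultimate representation: globally pooled final conv activations."""
        return self.pool.forward(self.features.forward(x))

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.embed(x))

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer) -> float:
        loss, dlogits = cross_entropy(self.logits(x), y)
        optimizer.zero_grad()
        dpool = self.head.backward(dlogits)
        self.features.backward(self.pool.backward(dpool))
        optimizer.step()
        return loss

    def parameters(self):
        yield from self.features.parameters()
        for name in self.head.params:
            yield f"head.{name}", self.head, name

    def state_dict(self) -> dict:
        state = {f"features.{k}": v for k, v in self.features.state_dict().items()}
        for name in self.head.params:
            state[f"head.{name}"] = self.head.params[name].copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.features.load_state_dict(
            {k[len("features."):]: v for k, v in state.items() if k.startswith("features.")})
        for name in self.head.params:
            self.head.params[name] = state[f"head.{name}"].copy()
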