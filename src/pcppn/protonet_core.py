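"""The part-prototype network.

A convolutional stack ``f`` (backbone plus two 1x1 add-on layers, the second
ending in a sigmoid so patch embeddings lie in (0, 1)) maps an image to an
``Hf x Wf x D`` grid of patch embeddings. A prototype layer holds M learned
vectors p_j in the same space, each owned by one pseudo-class. For every
prototype the squared Euclidean distance to each patch gives an activation
map of similarities

    s = log((d^2 + 1) / (d^2 + eps)),   eps = 1e-4 by default,

whose spatial max is that prototype's similarity score. A fully connected
layer plus softmax (``h``) turns the M scores into pseudo-class
probabilities. Distances are used in squared form throughout; no square root
is taken.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (Conv2d, ReLU, Sequential, Sigmoid, backbone_channels,
                 backbone_stride, build_backbone, softmax)
from .pseudo_class import PseudoLabelMap

CHECKPOINT_VERSION = 1


@dataclass
class NetworkConfig:
    """Architecture hyperparameters of the part-prototype network."""

    backbone: str = "tiny"
    input_side: int = 64
    D: int = 32                 # prototype / patch embedding depth
    M_per_class: int = 10       # prototypes allocated to each pseudo-class
    C: int = 4                  # number of pseudo-classes (= q * K)
    epsilon: float = 1e-4       # similarity stabilizer

    def __post_init__(self):
        if self.D < 1 or self.M_per_class < 1 or self.C < 1:
            raise ValueError("D, M_per_class and C must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def M(self) -> int:
        return self.M_per_class * self.C

    @property
    def feature_side(self) -> int:
        return self.input_side // backbone_stride(self.backbone)


@dataclass
class PrototypeBank:
    """The M prototype vectors, their owners, and (post-push) provenance."""

    vectors: np.ndarray                 # (M, D)
    owner: np.ndarray                   # (M,) pseudo-class id per prototype
    provenance: list = field(default_factory=list)  # (image id, row, col) or None

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        self.owner = np.asarray(self.owner, dtype=int)
        if self.vectors.ndim != 2 or len(self.owner) != self.vectors.shape[0]:
            raise ValueError("vectors must be (M, D) aligned with owner")
        if not self.provenance:
            self.provenance = [None] * self.vectors.shape[0]
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("prototype vectors must be finite")
        counts = np.bincount(self.owner)
        if len(set(counts[counts > 0])) > 1:
            raise ValueError("every pseudo-class must own the same number of prototypes")

    @property
    def M(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SimilarityProfile:
    """Per image: M x Hf x Wf activation grid, pooled scores, argmax cells."""

    activation: np.ndarray      # (M, Hf, Wf)
    scores: np.ndarray          # (M,)
    argmax_loc: np.ndarray      # (M, 2) row, col of maximizing patch


def similarity_from_distance(d2, epsilon: float = 1e-4):
    """log((d2 + 1) / (d2 + eps)): strictly decreasing in d2, -> 0 as d2 -> inf."""
    d2 = np.asarray(d2, dtype=np.float64)
    if np.any(d2 < 0):
        raise ValueError("squared distance must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = np.log(d2 + 1.0) - np.log(d2 + epsilon)
    return float(out) if out.ndim == 0 else out


def patch_distances(fm: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance of every prototype to every patch.

    fm: (D, Hf, Wf) or (B, D, Hf, Wf); vectors: (M, D).
    Returns (M, Hf, Wf) or (B, M, Hf, Wf); entries clipped at 0 against
    floating-point cancellation.
    """
    single = fm.ndim == 3
    z = fm[None] if single else fm
    if z.shape[1] != vectors.shape[1]:
        raise ValueError(
            f"depth mismatch: feature depth {z.shape[1]} vs prototype depth {vectors.shape[1]}")
    z = z.astype(np.float64)
    p = vectors.astype(np.float64)
    z2 = (z ** 2).sum(axis=1)[:, None]                       # (B,1,Hf,Wf)
    p2 = (p ** 2).sum(axis=1)[None, :, None, None]           # (1,M,1,1)
    cross = np.einsum("bdhw,md->bmhw", z, p, optimize=True)
    d2 = np.maximum(z2 + p2 - 2.0 * cross, 0.0)
    return d2[0] if single else d2


def pool_similarities(activation: np.ndarray) -> SimilarityProfile:
    """Max-pool each prototype's activation map; first max in row-major order."""
    if not np.all(np.isfinite(activation)):
        raise ValueError("activation must be finite")
    m, hf, wf = activation.shape
    flat = activation.reshape(m, -1)
    arg = flat.argmax(axis=1)
    scores = flat[np.arange(m), arg]
    locs = np.stack(np.unravel_index(arg, (hf, wf)), axis=1)
    return SimilarityProfile(activation=activation, scores=scores, argmax_loc=locs)


def classify_scores(scores: np.ndarray, head_w: np.ndarray) -> np.ndarray:
    """softmax(W_h @ scores) over pseudo-classes."""
    scores = np.asarray(scores, dtype=np.float64)
    if head_w.shape[1] != scores.shape[-1]:
        raise ValueError(f"head shape {head_w.shape} incompatible with {scores.shape}")
    return softmax(scores @ head_w.T)


class PCPPNet:
    """Backbone + add-on 1x1 convs + prototype layer + linear softmax head."""

    def __init__(self, cfg: NetworkConfig, pseudo_map: PseudoLabelMap | None = None,
                 seed: int = 0):
        self.cfg = cfg
        self.pseudo_map = pseudo_map
        rng = np.random.default_rng(seed)
        self.backbone = build_backbone(cfg.backbone, rng)
        cb = backbone_channels(cfg.backbone)
        # two add-on 1x1 convs; sigmoid bounds patch activations in (0,1),
        # matching the uniform [0,1) prototype initialization
        self.addon = Sequential([Conv2d(cb, cfg.D, 1, rng=rng), ReLU(),
                                 Conv2d(cfg.D, cfg.D, 1, rng=rng), Sigmoid()])
        owner = np.repeat(np.arange(cfg.C), cfg.M_per_class)
        self.bank = PrototypeBank(
            vectors=rng.uniform(0.0, 1.0, size=(cfg.M, cfg.D)).astype(np.float32),
            owner=owner)
        # head initialized +1 for own-class links, -0.5 otherwise
        w = np.full((cfg.C, cfg.M), -0.5, dtype=np.float32)
        w[owner[None, :] == np.arange(cfg.C)[:, None]] = 1.0
        self.head_w = w

    # -- forward ---------------------------------------------------------

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """(B,3,S,S) -> (B,D,Hf,Wf) patch-embedding grid."""
        if x.shape[-1] != self.cfg.input_side or x.shape[-2] != self.cfg.input_side:
            raise ValueError(
                f"expected input side {self.cfg.input_side}, got {x.shape[-2:]}")
        return self.addon.forward(self.backbone.forward(x))

    def forward(self, x: np.ndarray):
        """Returns (probs (B,C), scores (B,M), d2 (B,M,Hf,Wf), z (B,D,Hf,Wf))."""
        z = self.forward_features(x)
        d2 = patch_distances(z, self.bank.vectors)
        b, m = d2.shape[:2]
        d2min = d2.reshape(b, m, -1).min(axis=2)
        scores = similarity_from_distance(d2min, self.cfg.epsilon)
        probs = classify_scores(scores, self.head_w)
        return probs, scores, d2, z

    def similarity_profile(self, x1: np.ndarray) -> SimilarityProfile:
        """Full activation grid for a single image (3,S,S)."""
        z = self.forward_features(x1[None])
        d2 = patch_distances(z[0], self.bank.vectors)
        act = similarity_from_distance(d2, self.cfg.epsilon)
        return pool_similarities(act)

    # -- persistence -----------------------------------------------------

    def state_dict(self) -> dict:
        state = {f"backbone.{k}": v for k, v in self.backbone.state_dict().items()}
        state.update({f"addon.{k}": v for k, v in self.addon.state_dict().items()})
        state["prototypes"] = self.bank.vectors.copy()
        state["head_w"] = self.head_w.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.backbone.load_state_dict(
            {k[len("backbone."):]: v for k, v in state.items() if k.startswith("backbone.")})
        self.addon.load_state_dict(
            {k[len("addon."):]: v for k, v in state.items() if k.startswith("addon.")})
        self.bank.vectors = state["prototypes"].astype(np.float32).copy()
        self.head_w = state["head_w"].astype(np.float32).copy()

    def checksum(self, which: str = "all") -> str:
        """Hex digest of a parameter group ('backbone+proto', 'head', 'all')."""
        import hashlib
        h = hashlib.sha256()
        state = self.state_dict()
        keys = sorted(state)
        if which == "head":
            keys = ["head_w"]
        elif which == "backbone+proto":
            keys = [k for k in keys if k != "head_w"]
        for k in keys:
            h.update(k.encode())
            h.update(np.ascontiguousarray(state[k]).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.cfg),
            "pseudo_map": None if self.pseudo_map is None else self.pseudo_map.to_dict(),
            "owner": self.bank.owner.tolist(),
            "provenance": [list(p) if p is not None else None
                           for p in self.bank.provenance],
        }
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with open(path, "wb") as fh:
            header = json.dumps(meta).encode()
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "PCPPNet":
        with open(path, "rb") as fh:
            hlen = int.from_bytes(fh.read(8), "little")
            meta = json.loads(fh.read(hlen).decode())
            blob = io.BytesIO(fh.read())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = NetworkConfig(**meta["config"])
        pmap = None if meta["pseudo_map"] is None else PseudoLabelMap.from_dict(meta["pseudo_map"])
        net = cls(cfg, pseudo_map=pmap, seed=0)
        with np.load(blob) as npz:
            net.load_state_dict({k: npz[k] for k in npz.files})
        net.bank.owner = np.asarray(meta["owner"], dtype=int)
        net.bank.provenance = [tuple(p) if p is not None else None
                               for p in meta["provenance"]]
        return net
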