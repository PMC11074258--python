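"""Pseudo-class generation: deep embeddings, per-class K-means, remapping.

A black-box CNN classifier is trained on the original classes; its
penultimate (globally pooled) activations place every image in a latent
space. K-means is then run separately inside each class, and each (class,
cluster) pair becomes a pseudo-class with the fixed encoding
``pseudo = class * K + cluster``. The inverse mapping (integer division by
K) recovers the original class at inference time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .imageset_io import LabeledImageSet
from .nn import Adam, ConvClassifier


@dataclass
class PseudoLabelMap:
    """Bijection between (class, cluster) pairs and pseudo-class ids."""

    q: int
    K: int

    def __post_init__(self):
        if self.q < 1 or self.K < 1:
            raise ValueError("q and K must be >= 1")

    @property
    def n_pseudo(self) -> int:
        return self.q * self.K

    def forward(self, c: int, k: int) -> int:
        if not (0 <= c < self.q and 0 <= k < self.K):
            raise ValueError(f"(c={c}, k={k}) outside [0,{self.q}) x [0,{self.K})")
        return c * self.K + k

    def inverse(self, pseudo_id: int) -> int:
        if not 0 <= pseudo_id < self.n_pseudo:
            raise ValueError(f"pseudo id {pseudo_id} outside [0, {self.n_pseudo})")
        return pseudo_id // self.K

    def to_dict(self) -> dict:
        return {"q": self.q, "K": self.K,
                "inverse": [self.inverse(p) for p in range(self.n_pseudo)]}

    @classmethod
    def from_dict(cls, d: dict) -> "PseudoLabelMap":
        m = cls(q=int(d["q"]), K=int(d["K"]))
        if "inverse" in d and [m.inverse(p) for p in range(m.n_pseudo)] != list(d["inverse"]):
            raise ValueError("inverse table inconsistent with (q, K) encoding")
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PseudoLabelMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class LatentFeatureMatrix:
    """n x d embedding matrix aligned 1:1 with image ids."""

    features: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] != len(self.ids):
            raise ValueError("features must be (n, d) aligned with ids")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("embeddings must be finite")

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class EmbeddingTrainConfig:
    backbone: str = "tiny"
    epochs: int = 5
    lr: float = 0.001
    batch_size: int = 32
    seed: int = 0


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_embedding_backbone(train_ds: LabeledImageSet,
                             cfg: EmbeddingTrainConfig | None = None) -> ConvClassifier:
    """Train the black-box classifier whose latent space drives clustering."""
    cfg = cfg or EmbeddingTrainConfig()
    q = train_ds.q
    if q < 2 or len(np.unique(train_ds.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    model = ConvClassifier(cfg.backbone, q, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    x = train_ds.as_tensor()
    y = train_ds.labels
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.epochs):
        for idx in _batches(train_ds.n, cfg.batch_size, rng):
            model.train_step(x[idx], y[idx], opt)
    return model


def extract_embeddings(model: ConvClassifier, ds: LabeledImageSet,
                       batch_size: int = 64) -> LatentFeatureMatrix:
    """Penultimate-layer embedding (global-pooled conv activations) per image."""
    x = ds.as_tensor()
    if x.shape[-1] < 16 or x.shape[-2] < 16:
        raise ValueError(f"image size {x.shape[-2:]} too small for the backbone")
    rows = [model.embed(x[i:i + batch_size]) for i in range(0, ds.n, batch_size)]
    return LatentFeatureMatrix(features=np.concatenate(rows, axis=0), ids=list(ds.ids))


def _canonicalize(assign: np.ndarray, feats: np.ndarray, K: int) -> np.ndarray:
    """Relabel clusters by descending size, ties broken by centroid lex order."""
    order_keys = []
    for k in range(K):
        members = feats[assign == k]
        centroid = members.mean(axis=0) if len(members) else np.full(feats.shape[1], np.inf)
        order_keys.append((-len(members), tuple(np.round(centroid, 9))))
    new_of_old = {old: new for new, old in
                  enumerate(sorted(range(K), key=lambda k: order_keys[k]))}
    return np.array([new_of_old[a] for a in assign], dtype=int)


def cluster_per_class(feats: LatentFeatureMatrix, labels: np.ndarray, K: int,
                      seed: int = 0) -> np.ndarray:
    """K-means separately within each class; returns cluster index in [0, K)."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != feats.features.shape[0]:
        raise ValueError("labels must align with feature rows")
    clusters = np.full(len(labels), -1, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < K:
            raise ValueError(f"class {c} has {len(idx)} members, fewer than K={K}")
        sub = feats.features[idx]
        if K == 1:
            clusters[idx] = 0
            continue
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        assign = km.fit_predict(sub)
        clusters[idx] = _canonicalize(assign, sub, K)
    return clusters


def make_pseudo_labels(labels: np.ndarray, clusters: np.ndarray, K: int
                       ) -> tuple[np.ndarray, PseudoLabelMap]:
    """pseudo = class * K + cluster; returns labels plus the bijective map."""
    labels = np.asarray(labels, dtype=int)
    clusters = np.asarray(clusters, dtype=int)
    if clusters.min() < 0 or clusters.max() >= K:
        raise ValueError("cluster indices must lie in [0, K)")
    q = int(labels.max()) + 1
    pmap = PseudoLabelMap(q=q, K=K)
    return labels * K + clusters, pmap


def remap(pseudo_id: int, pmap: PseudoLabelMap) -> int:
    """Predicted pseudo-class -> originating original class."""
    return pmap.inverse(int(pseudo_id))
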