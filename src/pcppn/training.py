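"""Three-stage optimization of the part-prototype network.

Stage 1 (joint): with the head frozen, the conv stack and the prototypes
minimize, over the n training images,

    (1/n) sum_i [ CE(h(s_i), y~_i)
                  + lambda1 * min_{j: p_j in P_{y~_i}} d_j^(i)
                  - lambda2 * min_{j: p_j not in P_{y~_i}} d_j^(i) ]

where d_j^(i) is the squared distance from prototype j to its nearest patch
of image i. The cluster term pulls some patch of every image toward a
prototype of its own pseudo-class; the separation term pushes patches away
from other classes' prototypes.

Stage 2 (push): every prototype is replaced by the nearest patch embedding
among training images of its own pseudo-class, recording provenance.

Stage 3 (head): with conv and prototypes frozen, the fully connected head
is refit on cached similarity scores under cross-entropy plus an L1 penalty
on connections between a prototype and the output units of other
pseudo-classes.

The schedule [joint x joint_epochs -> push -> head x head_iters] repeats
until total_epochs joint epochs are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imageset_io import LabeledImageSet
from .nn import Adam, ArrayAdam, cross_entropy
from .protonet_core import NetworkConfig, PCPPNet, patch_distances, similarity_from_distance
from .pseudo_class import PseudoLabelMap


@dataclass
class TrainingConfig:
    lambda1: float = 0.8        # cluster-term weight
    lambda2: float = 0.08       # separation-term weight
    joint_epochs_before_push: int = 10
    head_iters: int = 20
    total_epochs: int = 30
    lr: float = 0.001
    head_l1: float = 1e-4       # sparsity on wrong-class head weights
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be >= 0")
        if min(self.joint_epochs_before_push, self.head_iters, self.total_epochs) < 1:
            raise ValueError("epochs/iters must be >= 1")


def _forward_terms(model: PCPPNet, x: np.ndarray, y: np.ndarray):
    """Shared forward pass; returns everything both loss and backward need."""
    owner = model.bank.owner
    missing = set(np.unique(y)) - set(owner.tolist())
    if missing:
        raise ValueError(f"pseudo-classes {sorted(missing)} own no prototype")
    z = model.forward_features(x)
    d2 = patch_distances(z, model.bank.vectors)          # (B,M,Hf,Wf)
    b, m, hf, wf = d2.shape
    flat = d2.reshape(b, m, -1)
    argpatch = flat.argmin(axis=2)                       # nearest patch per (i,j)
    d2min = flat[np.arange(b)[:, None], np.arange(m)[None, :], argpatch]
    scores = similarity_from_distance(d2min, model.cfg.epsilon)
    logits = scores @ model.head_w.T.astype(np.float64)
    ce, dlogits = cross_entropy(logits, y)

    own = owner[None, :] == y[:, None]                   # (B, M)
    d2_own = np.where(own, d2min, np.inf)
    d2_other = np.where(own, np.inf, d2min)
    j_own = d2_own.argmin(axis=1)
    j_other = d2_other.argmin(axis=1)
    cluster = d2_own[np.arange(b), j_own]
    separation = d2_other[np.arange(b), j_other]
    return dict(z=z, d2=d2, d2min=d2min, argpatch=argpatch, scores=scores,
                dlogits=dlogits, ce=ce, cluster=cluster, separation=separation,
                j_own=j_own, j_other=j_other, shape=(b, m, hf, wf))


def joint_loss(model: PCPPNet, x: np.ndarray, y: np.ndarray, cfg: TrainingConfig):
    """Eq.-style three-term objective; returns (loss, components dict)."""
    t = _forward_terms(model, x, np.asarray(y, dtype=int))
    comps = {"ce": t["ce"],
             "cluster": float(t["cluster"].mean()),
             "separation": float(t["separation"].mean())}
    loss = comps["ce"] + cfg.lambda1 * comps["cluster"] - cfg.lambda2 * comps["separation"]
    return float(loss), comps


def _joint_step(model: PCPPNet, x: np.ndarray, y: np.ndarray, cfg: TrainingConfig,
                opt_conv: Adam, opt_proto: ArrayAdam):
    """One minibatch update of conv + prototypes (head frozen)."""
    y = np.asarray(y, dtype=int)
    t = _forward_terms(model, x, y)
    b, m, hf, wf = t["shape"]
    d2min, z = t["d2min"], t["z"]
    p = model.bank.vectors.astype(np.float64)

    # gradient wrt the per-(image, prototype) minimal squared distance
    dscores = t["dlogits"] @ model.head_w.astype(np.float64)         # (B,M)
    dsdd2 = 1.0 / (d2min + 1.0) - 1.0 / (d2min + model.cfg.epsilon)
    dd2min = dscores * dsdd2
    rows = np.arange(b)
    np.add.at(dd2min, (rows, t["j_own"]), cfg.lambda1 / b)
    np.add.at(dd2min, (rows, t["j_other"]), -cfg.lambda2 / b)

    # scatter to the argmin patch cell of each (image, prototype)
    dD2 = np.zeros((b, m, hf * wf))
    dD2[rows[:, None], np.arange(m)[None, :], t["argpatch"]] = dd2min
    dD2 = dD2.reshape(b, m, hf, wf)

    zd = z.astype(np.float64)
    dz = 2.0 * (zd * dD2.sum(axis=1)[:, None]
                - np.einsum("bjrc,jd->bdrc", dD2, p, optimize=True))
    dP = -2.0 * (np.einsum("bjrc,bdrc->jd", dD2, zd, optimize=True)
                 - dD2.sum(axis=(0, 2, 3))[:, None] * p)

    opt_conv.zero_grad()
    model.backbone.backward(model.addon.backward(dz.astype(np.float32)))
    opt_conv.step()
    opt_proto.step(model.bank.vectors, dP)

    loss = t["ce"] + cfg.lambda1 * t["cluster"].mean() - cfg.lambda2 * t["separation"].mean()
    return float(loss)


def _conv_handles(model: PCPPNet):
    for key, layer, name in model.backbone.parameters():
        yield f"backbone.{key}", layer, name
    for key, layer, name in model.addon.parameters():
        yield f"addon.{key}", layer, name


def train_joint(ds: LabeledImageSet, model: PCPPNet, cfg: TrainingConfig,
                epochs: int | None = None, rng: np.random.Generator | None = None,
                opt_conv: Adam | None = None, opt_proto: ArrayAdam | None = None):
    """Run the joint stage; head weights are bitwise untouched."""
    if ds.pseudo_labels is None:
        raise ValueError("joint training requires pseudo-labels")
    epochs = cfg.joint_epochs_before_push if epochs is None else epochs
    rng = rng or np.random.default_rng(cfg.seed)
    opt_conv = opt_conv or Adam(_conv_handles(model), lr=cfg.lr)
    opt_proto = opt_proto or ArrayAdam(model.bank.vectors.shape, lr=cfg.lr)
    x = ds.as_tensor()
    y = ds.pseudo_labels
    history = []
    for _ in range(epochs):
        order = rng.permutation(ds.n)
        losses = []
        for start in range(0, ds.n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            losses.append(_joint_step(model, x[idx], y[idx], cfg, opt_conv, opt_proto))
        history.append(float(np.mean(losses)))
    return history


def project_prototypes(ds_train: LabeledImageSet, model: PCPPNet,
                       batch_size: int = 32) -> None:
    """Replace each prototype by its nearest same-pseudo-class patch embedding.

    Provenance (image id, patch row, patch col) is recorded on the bank.
    Ties resolve to the first candidate in dataset order, row-major within
    an image, so the push is deterministic and idempotent.
    """
    if ds_train.pseudo_labels is None:
        raise ValueError("projection requires pseudo-labels")
    owner = model.bank.owner
    present = set(ds_train.pseudo_labels.tolist())
    empty = set(owner.tolist()) - present
    if empty:
        raise ValueError(f"pseudo-classes {sorted(empty)} have no training image")

    m = model.bank.M
    best_d2 = np.full(m, np.inf)
    best_vec = np.zeros_like(model.bank.vectors)
    best_prov: list = [None] * m
    x = ds_train.as_tensor()
    for start in range(0, ds_train.n, batch_size):
        sl = slice(start, min(start + batch_size, ds_train.n))
        z = model.forward_features(x[sl])                  # (b,D,Hf,Wf)
        d2 = patch_distances(z, model.bank.vectors)        # (b,M,Hf,Wf)
        b, _, hf, wf = d2.shape
        same = ds_train.pseudo_labels[sl][:, None] == owner[None, :]
        d2 = np.where(same[:, :, None, None], d2, np.inf)
        flat = d2.transpose(1, 0, 2, 3).reshape(m, -1)     # (M, b*Hf*Wf)
        arg = flat.argmin(axis=1)
        val = flat[np.arange(m), arg]
        for j in np.flatnonzero(val < best_d2):
            bi, r, c = np.unravel_index(arg[j], (b, hf, wf))
            best_d2[j] = val[j]
            best_vec[j] = z[bi, :, r, c]
            best_prov[j] = (ds_train.ids[start + bi], int(r), int(c))
    model.bank.vectors = best_vec.astype(np.float32)
    model.bank.provenance = best_prov


def _all_scores(ds: LabeledImageSet, model: PCPPNet, batch_size: int = 64) -> np.ndarray:
    x = ds.as_tensor()
    out = []
    for start in range(0, ds.n, batch_size):
        z = model.forward_features(x[start:start + batch_size])
        d2 = patch_distances(z, model.bank.vectors)
        d2min = d2.reshape(d2.shape[0], d2.shape[1], -1).min(axis=2)
        out.append(similarity_from_distance(d2min, model.cfg.epsilon))
    return np.concatenate(out, axis=0)


def train_head(ds: LabeledImageSet, model: PCPPNet, cfg: TrainingConfig,
               scores: np.ndarray | None = None) -> list[float]:
    """Refit the head on cached scores (valid while conv and prototypes are
    frozen): head_iters full-batch Adam steps of CE + L1 on wrong-class links."""
    if ds.pseudo_labels is None:
        raise ValueError("head refit requires pseudo-labels")
    scores = _all_scores(ds, model) if scores is None else scores
    y = ds.pseudo_labels
    wrong = model.bank.owner[None, :] != np.arange(model.cfg.C)[:, None]  # (C,M)
    opt = ArrayAdam(model.head_w.shape, lr=cfg.lr)
    history = []
    for _ in range(cfg.head_iters):
        logits = scores @ model.head_w.T.astype(np.float64)
        ce, dlogits = cross_entropy(logits, y)
        w = model.head_w.astype(np.float64)
        loss = ce + cfg.head_l1 * np.abs(w[wrong]).sum()
        dW = dlogits.T @ scores + cfg.head_l1 * np.sign(w) * wrong
        opt.step(model.head_w, dW)
        history.append(float(loss))
    return history


def fit(ds_train: LabeledImageSet, ds_val: LabeledImageSet | None,
        net_cfg: NetworkConfig, train_cfg: TrainingConfig,
        pseudo_map: PseudoLabelMap | None = None):
    """Full schedule: cycles of [joint -> push -> head] until total_epochs.

    total_epochs counts joint epochs; push and head refits run once per
    cycle of joint_epochs_before_push. Returns (model, history dict).
    """
    if ds_train.pseudo_labels is None:
        raise ValueError("fit requires a pseudo-labeled training set")
    if pseudo_map is None:
        q = ds_train.q
        if net_cfg.C % q:
            raise ValueError(f"C={net_cfg.C} not a multiple of q={q}")
        pseudo_map = PseudoLabelMap(q=q, K=net_cfg.C // q)
    model = PCPPNet(net_cfg, pseudo_map=pseudo_map, seed=train_cfg.seed)
    rng = np.random.default_rng(train_cfg.seed)
    opt_conv = Adam(_conv_handles(model), lr=train_cfg.lr)
    opt_proto = ArrayAdam(model.bank.vectors.shape, lr=train_cfg.lr)

    history = {"joint_loss": [], "head_loss": [], "val_accuracy": []}
    done = 0
    while done < train_cfg.total_epochs:
        n_ep = min(train_cfg.joint_epochs_before_push, train_cfg.total_epochs - done)
        history["joint_loss"] += train_joint(ds_train, model, train_cfg, epochs=n_ep,
                                             rng=rng, opt_conv=opt_conv,
                                             opt_proto=opt_proto)
        done += n_ep
        project_prototypes(ds_train, model, batch_size=train_cfg.batch_size)
        history["head_loss"].append(train_head(ds_train, model, train_cfg))
        if ds_val is not None and ds_val.n:
            history["val_accuracy"].append(_remapped_accuracy(ds_val, model))
    return model, history


def _remapped_accuracy(ds: LabeledImageSet, model: PCPPNet,
                       batch_size: int = 64) -> float:
    scores = _all_scores(ds, model, batch_size)
    pseudo_pred = (scores @ model.head_w.T.astype(np.float64)).argmax(axis=1)
    pred = pseudo_pred // model.pseudo_map.K
    return float((pred == ds.labels).mean())


__all__ = ["TrainingConfig", "joint_loss", "train_joint", "project_prototypes",
           "train_head", "fit"]
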