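"""Image-set containers, manifest I/O, preprocessing, balancing, augmentation.

The manifest is a UTF-8 CSV with header ``id,filepath,label[,fold][,pseudo_label]``.
Labels are densely re-encoded to ``[0, q)`` on load (sorted by original label
value); the encoding table is retained on the dataset for reporting.

Preprocessing resizes every image to ``side x side x 3`` (bilinear,
anti-aliased), scales intensities to [0, 1] and standardizes each channel with
the fixed constants ``NORM_MEAN``/``NORM_STD``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import AffineTransform, resize, warp

#: per-channel standardization constants applied after scaling to [0, 1]
NORM_MEAN = (0.5, 0.5, 0.5)
NORM_STD = (0.25, 0.25, 0.25)

#: geometric operations understood by AugmentationSpec
AUG_OPS = ("rotation", "skew", "shear", "distortion")


@dataclass
class LabeledImageSet:
    """Images + class labels (+ optional pseudo-labels) + fold assignments."""

    images: list[np.ndarray]
    ids: list[str]
    labels: np.ndarray
    fold: np.ndarray
    pseudo_labels: np.ndarray | None = None
    label_encoding: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.fold = np.asarray(self.fold, dtype=int)
        if self.pseudo_labels is not None:
            self.pseudo_labels = np.asarray(self.pseudo_labels, dtype=int)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.images)

    @property
    def q(self) -> int:
        return int(self.labels.max()) + 1 if self.n else 0

    def validate(self) -> None:
        if not (len(self.images) == len(self.ids) == len(self.labels) == len(self.fold)):
            raise ValueError("images, ids, labels and fold must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("image ids must be unique")
        if self.n and (self.labels.min() < 0):
            raise ValueError("labels must be non-negative")
        dtypes = {im.dtype for im in self.images}
        if len(dtypes) > 1:
            raise ValueError(f"images must share one dtype, got {dtypes}")
        for i, im in enumerate(self.images):
            if im.ndim != 3 or im.shape[2] != 3:
                raise ValueError(
                    f"image {self.ids[i]!r} must be HxWx3, got shape {im.shape}")
        if self.pseudo_labels is not None:
            if len(self.pseudo_labels) != self.n:
                raise ValueError("pseudo_labels length mismatch")
            if self.n and self.pseudo_labels.min() < 0:
                raise ValueError("pseudo_labels must be non-negative")

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            ids=[self.ids[i] for i in idx],
            labels=self.labels[idx],
            fold=self.fold[idx],
            pseudo_labels=None if self.pseudo_labels is None else self.pseudo_labels[idx],
            label_encoding=dict(self.label_encoding),
        )

    def with_pseudo_labels(self, pseudo: np.ndarray) -> "LabeledImageSet":
        return replace(self, pseudo_labels=np.asarray(pseudo, dtype=int))

    def as_tensor(self) -> np.ndarray:
        """Stack into a (n, 3, H, W) float32 batch (requires uniform size)."""
        arr = np.stack(self.images).astype(np.float32)
        return np.transpose(arr, (0, 3, 1, 2))


@dataclass
class AugmentationSpec:
    """Geometric augmentation: which ops, their ranges, copies per image."""

    ops: tuple = AUG_OPS
    multiplier: int = 4
    seed: int = 0
    rotation_deg: float = 25.0
    shear_deg: float = 10.0
    skew_frac: float = 0.10
    distortion_alpha: float = 2.0
    distortion_sigma: float = 8.0
    keep_originals: bool = True

    def __post_init__(self):
        self.ops = tuple(self.ops)
        unknown = set(self.ops) - set(AUG_OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        for name in ("rotation_deg", "shear_deg", "skew_frac", "distortion_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def load_manifest(manifest_path, image_root) -> LabeledImageSet:
    """Read a manifest CSV and its images into a LabeledImageSet."""
    manifest_path = Path(manifest_path)
    image_root = Path(image_root)
    df = pd.read_csv(manifest_path, dtype={"id": str, "filepath": str})
    required = {"id", "filepath", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    raw_labels = df["label"].tolist()
    uniq = sorted(set(raw_labels), key=str)
    encoding = {lab: i for i, lab in enumerate(uniq)}
    labels = np.array([encoding[lab] for lab in raw_labels], dtype=int)

    images = []
    for rid, rel in zip(df["id"], df["filepath"]):
        path = image_root / rel
        if not path.exists():
            raise FileNotFoundError(f"image file for id {rid!r} not found: {path}")
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
        images.append(arr)

    fold = df["fold"].to_numpy(dtype=int) if "fold" in df else np.zeros(len(df), dtype=int)
    pseudo = df["pseudo_label"].to_numpy(dtype=int) if "pseudo_label" in df else None
    return LabeledImageSet(images=images, ids=df["id"].tolist(), labels=labels,
                           fold=fold, pseudo_labels=pseudo, label_encoding=encoding)


def save_manifest(ds: LabeledImageSet, manifest_path, image_root=None) -> None:
    """Write the manifest CSV; if image_root is given, also write PNGs."""
    manifest_path = Path(manifest_path)
    rows = {"id": ds.ids, "filepath": [f"{i}.png" for i in ds.ids],
            "label": ds.labels, "fold": ds.fold}
    if ds.pseudo_labels is not None:
        rows["pseudo_label"] = ds.pseudo_labels
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    if image_root is not None:
        image_root = Path(image_root)
        image_root.mkdir(parents=True, exist_ok=True)
        for rid, im in zip(ds.ids, ds.images):
            if im.dtype != np.uint8:
                im = np.clip(denormalize(im) * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(im).save(image_root / f"{rid}.png")


def normalize(img01: np.ndarray) -> np.ndarray:
    mean = np.asarray(NORM_MEAN, dtype=np.float32)
    std = np.asarray(NORM_STD, dtype=np.float32)
    return ((img01 - mean) / std).astype(np.float32)


def denormalize(img: np.ndarray) -> np.ndarray:
    mean = np.asarray(NORM_MEAN, dtype=np.float32)
    std = np.asarray(NORM_STD, dtype=np.float32)
    return img * std + mean


def preprocess(ds: LabeledImageSet, side: int) -> LabeledImageSet:
    """Resize every image to side x side x 3 and standardize intensities."""
    if side < 32:
        raise ValueError("side must be >= 32")
    out = []
    for rid, im in zip(ds.ids, ds.images):
        if im.ndim != 3 or im.shape[2] != 3:
            raise ValueError(f"image {rid!r} must have 3 channels")
        img01 = im.astype(np.float32) / 255.0 if im.dtype == np.uint8 else im.astype(np.float32)
        if im.shape[0] != side or im.shape[1] != side:
            img01 = resize(img01, (side, side, 3), order=1, anti_aliasing=True,
                           preserve_range=True).astype(np.float32)
        out.append(normalize(img01))
    return replace(ds, images=out)


def _groups(ds: LabeledImageSet, key: str) -> dict[int, np.ndarray]:
    if key == "label":
        vec = ds.labels
    elif key == "pseudo_label":
        if ds.pseudo_labels is None:
            raise ValueError("dataset has no pseudo_labels")
        vec = ds.pseudo_labels
    else:
        raise ValueError("key must be 'label' or 'pseudo_label'")
    return {int(g): np.flatnonzero(vec == g) for g in np.unique(vec)}


def balance_by_oversampling(ds: LabeledImageSet, target_per_class: int,
                            key: str = "label", seed: int = 0) -> LabeledImageSet:
    """Oversample (with replacement) every group below the target count.

    Groups already at or above the target are left unchanged. Duplicated
    entries get ids suffixed ``{src}#dup{k}`` so provenance stays auditable.
    """
    groups = _groups(ds, key)
    for g, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {g} under key {key!r} is empty")
    rng = np.random.default_rng(seed)
    extra_idx: list[int] = []
    for g in sorted(groups):
        idx = groups[g]
        deficit = target_per_class - len(idx)
        if deficit > 0:
            extra_idx.extend(rng.choice(idx, size=deficit, replace=True).tolist())

    dup_count: dict[str, int] = {}
    images = list(ds.images)
    ids = list(ds.ids)
    labels = list(ds.labels)
    fold = list(ds.fold)
    pseudo = None if ds.pseudo_labels is None else list(ds.pseudo_labels)
    for i in extra_idx:
        src = ds.ids[i]
        dup_count[src] = dup_count.get(src, 0) + 1
        images.append(ds.images[i])
        ids.append(f"{src}#dup{dup_count[src]}")
        labels.append(ds.labels[i])
        fold.append(ds.fold[i])
        if pseudo is not None:
            pseudo.append(ds.pseudo_labels[i])
    return LabeledImageSet(images=images, ids=ids, labels=np.array(labels),
                           fold=np.array(fold),
                           pseudo_labels=None if pseudo is None else np.array(pseudo),
                           label_encoding=dict(ds.label_encoding))


def _augment_one(im: np.ndarray, spec: AugmentationSpec,
                 rng: np.random.Generator) -> np.ndarray:
    h, w = im.shape[:2]
    img = im.astype(np.float32)
    center = np.array([w, h]) / 2.0 - 0.5

    rot = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg)) \
        if "rotation" in spec.ops else 0.0
    shear = np.deg2rad(rng.uniform(-spec.shear_deg, spec.shear_deg)) \
        if "shear" in spec.ops else 0.0
    if "skew" in spec.ops:
        sx = 1.0 + rng.uniform(-spec.skew_frac, spec.skew_frac)
        sy = 1.0 + rng.uniform(-spec.skew_frac, spec.skew_frac)
    else:
        sx = sy = 1.0

    shift_to = AffineTransform(translation=-center)
    tform = AffineTransform(rotation=rot, shear=shear, scale=(sx, sy))
    shift_back = AffineTransform(translation=center)
    out = warp(img, (shift_to + tform + shift_back).inverse, order=1,
               mode="reflect", preserve_range=True).astype(np.float32)

    if "distortion" in spec.ops and spec.distortion_alpha > 0:
        dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), spec.distortion_sigma,
                             mode="reflect") * spec.distortion_alpha
        dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), spec.distortion_sigma,
                             mode="reflect") * spec.distortion_alpha
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        warped = np.empty_like(out)
        for ch in range(3):
            warped[..., ch] = map_coordinates(out[..., ch], [rr + dy, cc + dx],
                                              order=1, mode="reflect")
        out = warped

    if im.dtype == np.uint8:
        return np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def augment(ds: LabeledImageSet, spec: AugmentationSpec) -> LabeledImageSet:
    """Append ``multiplier`` warped copies per image (originals kept by default).

    Deterministic for a fixed (dataset order, spec.seed). Copies carry ids
    ``{src}#aug{k}`` and inherit labels, pseudo-labels and fold.
    """
    rng = np.random.default_rng(spec.seed)
    images = list(ds.images) if spec.keep_originals else []
    ids = list(ds.ids) if spec.keep_originals else []
    keep = spec.keep_originals

    labels, fold = list(ds.labels) if keep else [], list(ds.fold) if keep else []
    pseudo = (list(ds.pseudo_labels) if keep else []) if ds.pseudo_labels is not None else None
    for i, im in enumerate(ds.images):
        for k in range(spec.multiplier):
            images.append(_augment_one(im, spec, rng))
            ids.append(f"{ds.ids[i]}#aug{k + 1}")
            labels.append(ds.labels[i])
            fold.append(ds.fold[i])
            if pseudo is not None:
                pseudo.append(ds.pseudo_labels[i])
    return LabeledImageSet(images=images, ids=ids, labels=np.array(labels),
                           fold=np.array(fold),
                           pseudo_labels=None if pseudo is None else np.array(pseudo),
                           label_encoding=dict(ds.label_encoding))


def source_id(image_id: str) -> str:
    """Strip ``#dup``/``#aug`` provenance suffixes to recover the original id."""
    return image_id.split("#", 1)[0]
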