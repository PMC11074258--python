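"""Prototype visualization and rater-based interpretability metrics.

The Relevancy metric converts a table of 0-3 rater scores (one row per
prototype, one column per rater) to a percentage:

    Relevancy = 100 / (M * P) * sum_{i,j} v_j^(i) / 3

Disagreement is the standard deviation of the raters' scores for each
prototype, averaged within class and overall. Both are pure functions of
the rating table; rating ingestion is file-based (CSV), no GUI.

The confounding probe is the automated, rater-free surrogate available on
synthetic data: it measures how often a prototype's explanation box
overlaps the planted class-discriminative motif of its source image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .imageset_io import LabeledImageSet, source_id
from .protonet_core import PCPPNet

VALID_SCORES = {0, 1, 2, 3}


@dataclass
class RatingTable:
    """M x P relevancy scores in {0,1,2,3}; rows = prototypes, cols = raters."""

    scores: np.ndarray
    prototype_ids: list[str]
    rater_ids: list[str]
    owners: np.ndarray | None = None    # optional class per prototype

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        m, p = self.scores.shape
        if len(self.prototype_ids) != m or len(self.rater_ids) != p:
            raise ValueError("ids must align with the score matrix")
        if not set(np.unique(self.scores)).issubset(VALID_SCORES):
            raise ValueError("scores must lie in {0, 1, 2, 3}")
        if self.owners is not None:
            self.owners = np.asarray(self.owners, dtype=int)
            if len(self.owners) != m:
                raise ValueError("owners must align with prototypes")

    @property
    def M(self) -> int:
        return self.scores.shape[0]

    @property
    def P(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_csv(cls, path, owners_path=None) -> "RatingTable":
        """Long-format CSV: prototype_id,rater_id,score."""
        df = pd.read_csv(path, dtype={"prototype_id": str, "rater_id": str})
        wide = df.pivot(index="prototype_id", columns="rater_id", values="score")
        if wide.isna().any().any():
            raise ValueError("rating table has missing (prototype, rater) cells")
        owners = None
        protos = [str(p) for p in wide.index]
        if owners_path is not None:
            odf = pd.read_csv(owners_path, dtype={"prototype_id": str})
            owners = odf.set_index("prototype_id")["owner"].reindex(protos).to_numpy(int)
        return cls(scores=wide.to_numpy(int), prototype_ids=protos,
                   rater_ids=[str(r) for r in wide.columns], owners=owners)

    def to_csv(self, path) -> None:
        rows = [(p, r, int(self.scores[i, j]))
                for i, p in enumerate(self.prototype_ids)
                for j, r in enumerate(self.rater_ids)]
        pd.DataFrame(rows, columns=["prototype_id", "rater_id", "score"]).to_csv(
            path, index=False)


@dataclass
class PrototypeExplanation:
    """A prototype rendered on its source image: heatmap + bounding box."""

    prototype_id: int
    source_image_id: str
    activation_upsampled: np.ndarray    # input-resolution heat values
    box: tuple                          # (row0, col0, row1, col1), exclusive end
    max_similarity: float


def relevancy(rt: RatingTable) -> float:
    """Mean score over all (prototype, rater) cells, scaled 0-3 -> 0-100."""
    return float(rt.scores.mean() / 3.0 * 100.0)


def relevancy_by_class(rt: RatingTable, owners: np.ndarray | None = None) -> dict:
    """Relevancy restricted to each class's prototypes; {} entries for classes
    with no prototypes are omitted rather than reported as 0."""
    owners = rt.owners if owners is None else np.asarray(owners, dtype=int)
    if owners is None:
        raise ValueError("owner class per prototype is required")
    if len(owners) != rt.M:
        raise ValueError("owners must align with prototypes")
    return {int(c): float(rt.scores[owners == c].mean() / 3.0 * 100.0)
            for c in np.unique(owners)}


def disagreement(rt: RatingTable, ddof: int = 1) -> dict:
    """Per-prototype std across raters (sample std by default), then averages."""
    if rt.P < 2:
        raise ValueError("disagreement needs at least 2 raters")
    per_proto = rt.scores.std(axis=1, ddof=ddof)
    out = {"per_prototype": per_proto, "overall": float(per_proto.mean())}
    if rt.owners is not None:
        out["per_class"] = {int(c): float(per_proto[rt.owners == c].mean())
                            for c in np.unique(rt.owners)}
    return out


def stability_summary(values_by_group: dict) -> pd.DataFrame:
    """Table-style summary of metric values across runs/backbones:
    one row per group with its values, mean, and sample std."""
    rows = []
    for group, values in values_by_group.items():
        values = np.asarray(values, dtype=float)
        if len(values) < 2:
            raise ValueError(f"group {group!r} needs at least 2 values")
        rows.append({"group": group, "values": values.tolist(),
                     "mean": float(values.mean()),
                     "std": float(values.std(ddof=1))})
    return pd.DataFrame(rows).set_index("group")


def explain_prototype(model: PCPPNet, ds: LabeledImageSet, j: int,
                      percentile: float = 95.0) -> PrototypeExplanation:
    """Render prototype j's activation on its provenance image.

    The activation grid is bilinearly upsampled to input resolution; the
    bounding box is the tight box around the region at or above the given
    percentile of the upsampled map.
    """
    prov = model.bank.provenance[j]
    if prov is None:
        raise ValueError(f"prototype {j} has no provenance; run projection first")
    img_id, _, _ = prov
    try:
        idx = ds.ids.index(img_id)
    except ValueError:
        # oversampling duplicates are pixel-identical to their source, so a
        # "#dup" provenance id may be resolved through the original image
        if "#aug" not in img_id and source_id(img_id) in ds.ids:
            idx = ds.ids.index(source_id(img_id))
        else:
            raise ValueError(f"provenance image {img_id!r} not in the given dataset")
    image = ds.images[idx]
    x = np.transpose(image.astype(np.float32), (2, 0, 1))
    profile = model.similarity_profile(x)
    side = model.cfg.input_side
    up = resize(profile.activation[j], (side, side), order=1,
                anti_aliasing=False, preserve_range=True)
    thresh = np.percentile(up, percentile)
    mask = up >= thresh
    rr, cc = np.nonzero(mask)
    box = (int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1)
    return PrototypeExplanation(prototype_id=j, source_image_id=img_id,
                                activation_upsampled=up, box=box,
                                max_similarity=float(profile.scores[j]))


def box_iou(a: tuple, b: tuple) -> float:
    """Intersection over union of (r0,c0,r1,c1) boxes with exclusive ends."""
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def confounding_probe(model: PCPPNet, ds: LabeledImageSet, truth: pd.DataFrame,
                      iou_threshold: float = 0.1) -> dict:
    """Fraction of prototypes whose explanation box overlaps the planted motif.

    ``truth`` is the fixture's ground-truth table (columns id,r0,c0,r1,c1).
    Prototypes whose provenance is a geometrically augmented copy are skipped
    (the motif coordinates no longer match); oversampled duplicates resolve
    to their source row. Raises if no provenance id has ground truth.
    """
    boxes = {str(r.id): (int(r.r0), int(r.c0), int(r.r1), int(r.c1))
             for r in truth.itertuples()}
    ious, skipped = {}, []
    for j in range(model.bank.M):
        prov = model.bank.provenance[j]
        if prov is None:
            raise ValueError(f"prototype {j} has no provenance; run projection first")
        sid = source_id(prov[0])
        if "#aug" in prov[0] or sid not in boxes:
            skipped.append(j)
            continue
        expl = explain_prototype(model, ds, j)
        ious[j] = box_iou(expl.box, boxes[sid])
    if not ious:
        raise ValueError("no prototype provenance matches the ground-truth table; "
                         "is this a synthetic fixture?")
    vals = np.array(list(ious.values()))
    return {"iou_per_prototype": ious,
            "fraction_overlapping": float((vals > iou_threshold).mean()),
            "mean_iou": float(vals.mean()),
            "n_scored": len(ious),
            "skipped_prototypes": skipped}


def overlay_figure(explanation: PrototypeExplanation, image: np.ndarray, path) -> None:
    """Save a PNG overlay of the activation heatmap and box on the image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    fig, ax = plt.subplots(figsize=(4, 4))
    show = image.astype(np.float32)
    if show.max() > 1.5:
        show = show / 255.0
    show = np.clip(show, 0.0, 1.0)
    ax.imshow(show)
    ax.imshow(explanation.activation_upsampled, cmap="jet", alpha=0.35)
    r0, c0, r1, c1 = explanation.box
    ax.add_patch(patches.Rectangle((c0, r0), c1 - c0, r1 - r0,
                                   edgecolor="yellow", facecolor="none", lw=2))
    ax.set_title(f"prototype {explanation.prototype_id} "
                 f"(s={explanation.max_similarity:.2f})")
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
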