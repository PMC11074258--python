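"""Prediction with pseudo-class remapping, confusion matrices, fold summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imageset_io import LabeledImageSet
from .protonet_core import PCPPNet, SimilarityProfile, classify_scores


@dataclass
class EvalReport:
    """Confusion matrix (rows = true class), per-class and pooled accuracies."""

    confusion: np.ndarray
    per_class_accuracy: np.ndarray      # percent; NaN for empty classes
    overall_accuracy: float             # percent, sample-weighted
    macro_accuracy: float               # percent, unweighted mean over classes
    fold: int = 0

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=int)
        q = self.confusion.shape[0]
        if self.confusion.shape != (q, q):
            raise ValueError("confusion must be square")
        if np.any(self.confusion < 0):
            raise ValueError("confusion entries must be >= 0")

    @property
    def q(self) -> int:
        return self.confusion.shape[0]

    def to_dict(self) -> dict:
        return {"confusion": self.confusion.tolist(),
                "per_class_accuracy": [None if np.isnan(a) else float(a)
                                       for a in self.per_class_accuracy],
                "overall_accuracy": self.overall_accuracy,
                "macro_accuracy": self.macro_accuracy,
                "fold": self.fold}


def predict(image: np.ndarray, model: PCPPNet):
    """Single image (3,S,S) -> (class id, pseudo id, SimilarityProfile).

    Pseudo argmax ties resolve to the lowest pseudo id (numpy argmax).
    """
    profile = model.similarity_profile(image)
    probs = classify_scores(profile.scores, model.head_w)
    pseudo = int(np.argmax(probs))
    cls = model.pseudo_map.inverse(pseudo) if model.pseudo_map is not None else pseudo
    return cls, pseudo, profile


def predict_batch(ds: LabeledImageSet, model: PCPPNet, batch_size: int = 64):
    """Vectorized prediction; returns (classes, pseudo ids)."""
    x = ds.as_tensor()
    pseudo = []
    for start in range(0, ds.n, batch_size):
        probs, _, _, _ = model.forward(x[start:start + batch_size])
        pseudo.append(probs.argmax(axis=1))
    pseudo = np.concatenate(pseudo)
    if model.pseudo_map is not None:
        classes = pseudo // model.pseudo_map.K
    else:
        classes = pseudo
    return classes, pseudo


def confusion_matrix(true: np.ndarray, pred: np.ndarray, q: int) -> np.ndarray:
    cm = np.zeros((q, q), dtype=int)
    np.add.at(cm, (np.asarray(true, dtype=int), np.asarray(pred, dtype=int)), 1)
    return cm


def report_from_predictions(true: np.ndarray, pred: np.ndarray, q: int,
                            fold: int = 0) -> EvalReport:
    cm = confusion_matrix(true, pred, q)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, 100.0 * np.diag(cm) / row, np.nan)
    overall = 100.0 * np.diag(cm).sum() / max(cm.sum(), 1)
    macro = float(np.nanmean(per_class)) if np.any(row > 0) else float("nan")
    return EvalReport(confusion=cm, per_class_accuracy=per_class,
                      overall_accuracy=float(overall), macro_accuracy=macro, fold=fold)


def evaluate(test_ds: LabeledImageSet, model: PCPPNet, fold: int = 0,
             batch_size: int = 64) -> EvalReport:
    """Remapped predictions scored against the original class labels."""
    classes, _ = predict_batch(test_ds, model, batch_size)
    q = model.pseudo_map.q if model.pseudo_map is not None else test_ds.q
    q = max(q, test_ds.q)
    return report_from_predictions(test_ds.labels, classes, q, fold=fold)


def cross_fold_summary(reports: list[EvalReport]) -> dict:
    """Mean +/- sample std (ddof=1) of each metric across folds, plus the
    count- and rate-averaged confusion matrices."""
    if len(reports) < 2:
        raise ValueError("need at least 2 fold reports")
    q = reports[0].q
    if any(r.q != q for r in reports):
        raise ValueError("all reports must share the same number of classes")

    def _ms(values):
        arr = np.asarray(values, dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            return {"mean": float(arr.mean()) if len(arr) else None, "std": None}
        return {"mean": float(arr.mean()), "std": float(arr.std(ddof=1))}

    per_class = {f"class_{c}_accuracy": _ms([r.per_class_accuracy[c] for r in reports])
                 for c in range(q)}
    counts = np.stack([r.confusion for r in reports]).astype(float)
    rates = np.stack([r.confusion / np.maximum(r.confusion.sum(axis=1, keepdims=True), 1)
                      for r in reports])
    return {"overall_accuracy": _ms([r.overall_accuracy for r in reports]),
            "macro_accuracy": _ms([r.macro_accuracy for r in reports]),
            **per_class,
            "mean_confusion_counts": counts.mean(axis=0).tolist(),
            "mean_confusion_rates": rates.mean(axis=0).tolist()}
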