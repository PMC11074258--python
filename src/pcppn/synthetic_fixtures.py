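"""Desk-scale synthetic image sets with planted, clusterable structure.

Each of the q classes is composed of ``K_true`` visually distinct sub-modes.
Every image carries exactly one square motif — an oriented sinusoidal
grating with a family-specific orientation, spatial frequency and color
tint, the family being determined by (class, sub-mode) — placed at a random
location over a noisy gray background. When the confound flag is on, the
background itself receives a class-correlated color tint, giving models a
shortcut that is not the discriminative motif. A sidecar ground-truth table
records (class, sub-mode, motif bounding box) per image so prototype
explanations can be scored for motif overlap without human raters.

This emulates the structure of a histopathology set such as BreakHis —
few diagnostic classes, each containing several histological sub-types,
with slide-level color variation as a potential confounder — while staying
small enough to train on a CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imageset_io import LabeledImageSet
from .interpretability import RatingTable

#: distinct color tints for motif families (cycled if more families)
_PALETTE = [
    (1.00, 0.35, 0.35), (0.35, 1.00, 0.35), (0.40, 0.40, 1.00),
    (1.00, 1.00, 0.30), (1.00, 0.35, 1.00), (0.35, 1.00, 1.00),
    (1.00, 0.65, 0.30), (0.65, 0.30, 1.00),
]

#: per-class background tints used only when the confound is on
_CLASS_TINTS = [
    (0.12, 0.0, -0.06), (-0.06, 0.0, 0.12), (0.0, 0.12, -0.06),
    (0.12, -0.06, 0.0), (-0.06, 0.12, 0.0), (0.0, -0.06, 0.12),
]


@dataclass
class SynthSpec:
    """Parameters of the planted-image generator."""

    q: int = 2
    K_true: int = 2
    n_per_mode: int = 25
    side: int = 64
    motif_size: int = 28
    confound: bool = False
    confound_strength: float = 0.5
    noise_sd: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if not 0 < self.motif_size < self.side:
            raise ValueError("motif_size must lie in (0, side)")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must lie in [0, 1]")


def _motif(family: int, n_families: int, size: int) -> np.ndarray:
    """Oriented color grating for one (class, sub-mode) family; (size,size,3).

    Families differ along several axes at once — orientation, spatial
    frequency, color tint and mean luminance — so that any two families are
    well separated in generic pooled convolutional features.
    """
    theta = np.pi * family / n_families
    # frequencies stay well below the coarsest sampling rate of typical
    # strided backbones (period >= ~7 px) so pooled conv features do not
    # alias with the motif's random position
    freq = 0.06 + 0.03 * family          # cycles per pixel
    u, v = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    phase = 2 * np.pi * freq * (u * np.cos(theta) + v * np.sin(theta))
    base = 0.40 + 0.45 * (family % 2)    # alternate dark / bright families
    grating = base + 0.30 * np.sin(phase)
    color = np.asarray(_PALETTE[family % len(_PALETTE)])
    return np.clip(grating[:, :, None] * color[None, None, :], 0.0, 1.0)


def generate_imageset(spec: SynthSpec) -> tuple[LabeledImageSet, pd.DataFrame]:
    """Generate q * K_true * n_per_mode images plus the ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    n_fam = spec.q * spec.K_true
    images, ids, labels, truth_rows = [], [], [], []
    folds = []
    i = 0
    for c in range(spec.q):
        for k in range(spec.K_true):
            fam = c * spec.K_true + k
            patch = _motif(fam, n_fam, spec.motif_size)
            for _ in range(spec.n_per_mode):
                img = np.full((spec.side, spec.side, 3), 0.55)
                if spec.confound:
                    tint = np.asarray(_CLASS_TINTS[c % len(_CLASS_TINTS)])
                    img += spec.confound_strength * tint[None, None, :]
                img += rng.normal(0.0, spec.noise_sd, img.shape)
                r0 = int(rng.integers(0, spec.side - spec.motif_size + 1))
                c0 = int(rng.integers(0, spec.side - spec.motif_size + 1))
                img[r0:r0 + spec.motif_size, c0:c0 + spec.motif_size] = (
                    patch + rng.normal(0.0, spec.noise_sd, patch.shape))
                img8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
                rid = f"s{i:05d}"
                images.append(img8)
                ids.append(rid)
                labels.append(c)
                folds.append(i % 5)     # round-robin fold assignment
                truth_rows.append({"id": rid, "label": c, "sub_mode": k,
                                   "family": fam, "r0": r0, "c0": c0,
                                   "r1": r0 + spec.motif_size,
                                   "c1": c0 + spec.motif_size})
                i += 1
    ds = LabeledImageSet(images=images, ids=ids, labels=np.array(labels),
                         fold=np.array(folds))
    return ds, pd.DataFrame(truth_rows)


def generate_ratings(M: int, P: int, relevant_fraction: float, seed: int = 0,
                     high_probs=(0.0, 0.05, 0.35, 0.60),
                     low_probs=(0.60, 0.30, 0.08, 0.02),
                     owners: np.ndarray | None = None) -> RatingTable:
    """Simulated 0-3 rater scores: a ``relevant_fraction`` of prototypes draw
    from the high-score distribution, the rest from the low-score one."""
    if M < 1 or P < 1:
        raise ValueError("M and P must be >= 1")
    if not 0.0 <= relevant_fraction <= 1.0:
        raise ValueError("relevant_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_rel = int(round(relevant_fraction * M))
    scores = np.empty((M, P), dtype=int)
    for j in range(M):
        probs = high_probs if j < n_rel else low_probs
        scores[j] = rng.choice(4, size=P, p=np.asarray(probs) / np.sum(probs))
    return RatingTable(scores=scores,
                       prototype_ids=[f"p{j}" for j in range(M)],
                       rater_ids=[f"r{i}" for i in range(P)],
                       owners=owners)
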