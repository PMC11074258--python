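"""Shared helpers for the test suite."""

import numpy as np

from pcppn import LabeledImageSet


def mini_pseudo_ds(n=8, seed=0, side=64):
    """Tiny pseudo-labeled dataset of random float images (4 pseudo-classes)."""
    rng = np.random.default_rng(seed)
    images = [rng.normal(size=(side, side, 3)).astype(np.float32) for _ in range(n)]
    return LabeledImageSet(images=images, ids=[f"m{i}" for i in range(n)],
                           labels=np.arange(n) % 2, fold=np.zeros(n, dtype=int),
                           pseudo_labels=np.arange(n) % 4)
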