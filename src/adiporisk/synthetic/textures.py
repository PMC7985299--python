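"""Synthetic texture patches for the tissue-compartment classifier.

Each generator mimics the coarse colour/brightness statistics of one H&E
compartment: adipose (bright vacuoles with thin pink septa), stroma (uniform
eosinophilic collagen), epithelium (dense basophilic nuclei) and empty glass
background.  They are separable by construction — deliberately so, since the
classifier contract is about plumbing (areas, percentages), not about
replicating a production histology classifier.
"""

from __future__ import annotations

import numpy as np

TEXTURE_KINDS = ("adipose", "stroma", "epithelium", "background")


def make_texture_patch(kind: str, size: int = 64,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Return a uint8 RGB ``size``×``size`` patch of the given compartment."""
    if rng is None:
        rng = np.random.default_rng(0)
    if kind == "adipose":
        img = np.full((size, size, 3), 246.0) + rng.normal(0, 3, (size, size, 3))
        # pink septa: a few random chords across the patch
        for _ in range(max(2, size // 16)):
            t = rng.uniform(0, np.pi)
            offs = rng.uniform(0, size)
            rows, cols = np.mgrid[0:size, 0:size]
            d = np.abs((cols - size / 2) * np.cos(t) + (rows - size / 2) * np.sin(t) + offs - size / 2)
            img[d < 1.5] = [224, 156, 184]
    elif kind == "stroma":
        img = np.full((size, size, 3), [222.0, 152.0, 182.0])
        rows = np.arange(size)[:, None]
        img += (8.0 * np.sin(rows / 5.0 + rng.uniform(0, 6)))[..., None]
        img += rng.normal(0, 6, (size, size, 3))
    elif kind == "epithelium":
        img = np.full((size, size, 3), [196.0, 150.0, 200.0])
        n = int(size * size * 0.02)
        ys = rng.integers(1, size - 1, n)
        xs = rng.integers(1, size - 1, n)
        for y, x in zip(ys, xs):  # dark nuclei blobs
            img[y - 1:y + 2, x - 1:x + 2] = [88, 60, 130]
        img += rng.normal(0, 5, (size, size, 3))
    elif kind == "background":
        img = np.full((size, size, 3), 252.0) + rng.normal(0, 1.5, (size, size, 3))
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    return np.clip(img, 0, 255).astype(np.uint8)
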