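"""Tissue-compartment classification and relative adipose area.

A random-forest classifier on hand-crafted colour/texture summaries labels
tiles as adipose, stroma, epithelium or background; the relative area of
adipose tissue is reported over the three tissue compartments (background is
excluded from the denominator).  The feature set is deliberately simple —
per-channel intensity statistics plus brightness fractions — which is
adequate for area fractions on tile grids and keeps the model deterministic
and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from skimage.color import rgb2gray
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .morphometry import CalibratedRaster

TISSUE_LABELS = ("adipose", "stroma", "epithelium")
MODEL_FORMAT_VERSION = 1


def patch_features(patch: np.ndarray) -> np.ndarray:
    """Colour/texture summary of one RGB tile."""
    img = patch.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    gray = rgb2gray(img)
    feats = []
    for c in range(3):
        feats.extend([img[..., c].mean(), img[..., c].std()])
    feats.extend([
        gray.mean(), gray.std(),
        float((gray > 0.85).mean()),          # bright (vacuole/glass) fraction
        float((gray < 0.45).mean()),          # dark (nuclei) fraction
        float(np.abs(np.diff(gray, axis=0)).mean()
              + np.abs(np.diff(gray, axis=1)).mean()),  # local roughness
    ])
    return np.array(feats)


@dataclass
class CompartmentModel:
    forest: RandomForestClassifier
    classes: tuple[str, ...]
    holdout_accuracy: float
    patch_size: int = 64

    def predict(self, patches: list[np.ndarray]) -> np.ndarray:
        X = np.stack([patch_features(p) for p in patches])
        return self.forest.predict(X)

    def save(self, path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                     "forest": self.forest, "classes": self.classes,
                     "holdout_accuracy": self.holdout_accuracy,
                     "patch_size": self.patch_size}, path)

    @classmethod
    def load(cls, path) -> "CompartmentModel":
        d = joblib.load(path)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported compartment-model file version")
        return cls(d["forest"], tuple(d["classes"]),
                   d["holdout_accuracy"], d["patch_size"])


@dataclass(frozen=True)
class CompartmentMap:
    """Tile-label grid plus per-compartment areas (µm²)."""

    label_grid: np.ndarray          # per-pixel string labels' integer codes
    classes: tuple[str, ...]
    area_um2: dict[str, float]

    @property
    def percent_adipose(self) -> float:
        tissue = sum(self.area_um2.get(k, 0.0) for k in TISSUE_LABELS)
        if tissue <= 0:
            raise ValueError("no tissue area classified")
        return 100.0 * self.area_um2.get("adipose", 0.0) / tissue

    def percent(self, label: str) -> float:
        tissue = sum(self.area_um2.get(k, 0.0) for k in TISSUE_LABELS)
        return 100.0 * self.area_um2.get(label, 0.0) / tissue


def train_compartment_classifier(
    patches: list[tuple[np.ndarray, str]],
    seed: int = 0,
    n_estimators: int = 100,
    holdout: float = 0.2,
) -> CompartmentModel:
    """Fit the tile classifier on labelled patches; reports holdout accuracy.

    Deterministic per ``seed``.  Raises on an empty or single-class
    training set.
    """
    if not patches:
        raise ValueError("empty training set")
    labels = sorted({lab for _, lab in patches})
    if len(labels) < 2:
        raise ValueError("training set must contain at least 2 classes")
    X = np.stack([patch_features(p) for p, _ in patches])
    y = np.array([lab for _, lab in patches])
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=holdout, random_state=seed, stratify=y)
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(Xtr, ytr)
    acc = float((forest.predict(Xte) == yte).mean())
    size = patches[0][0].shape[0]
    return CompartmentModel(forest, tuple(labels), acc, patch_size=size)


def classify_compartments(
    raster: CalibratedRaster,
    model: CompartmentModel,
    patch_size: int | None = None,
) -> CompartmentMap:
    """Tile-wise classification of a slide into compartments.

    Tiles (stride = patch size; the ragged right/bottom edge tiles are
    included with their true pixel extent) are classified and stitched into
    a per-pixel label grid; areas are pixel counts × calibration².
    """
    if not isinstance(model, CompartmentModel):
        raise TypeError("model must be a trained CompartmentModel")
    ps = patch_size or model.patch_size
    img = raster.pixels
    if img.ndim != 3:
        raise ValueError("classify_compartments expects an RGB raster")
    h, w = img.shape[:2]
    codes = {c: i for i, c in enumerate(model.classes)}
    grid = np.zeros((h, w), dtype=np.int8)
    tiles, spans = [], []
    for y0 in range(0, h, ps):
        for x0 in range(0, w, ps):
            tiles.append(img[y0:y0 + ps, x0:x0 + ps])
            spans.append((y0, x0))
    preds = model.predict(tiles)
    for (y0, x0), lab in zip(spans, preds):
        grid[y0:y0 + ps, x0:x0 + ps] = codes[lab]
    px_area = raster.microns_per_pixel ** 2
    area = {c: float(np.sum(grid == i) * px_area) for c, i in codes.items()}
    return CompartmentMap(label_grid=grid, classes=model.classes, area_um2=area)
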