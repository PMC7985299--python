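"""Crown-like structure (CLS) detection and density.

A CLS is an adipocyte surrounded by a rim of CD68-positive macrophages.  The
detector separates the DAB chromogen from hematoxylin by colour
deconvolution, thresholds the DAB channel, and scores each adipocyte by the
fraction of its peri-cellular annulus (split into arc bins) that is
CD68-positive.  Patient-level inflammation is the CLS count per 10 cm² of
adipose tissue, dichotomised at 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.color import rgb2hed
from skimage.draw import polygon as draw_polygon

from .morphometry import AdipocyteObject

CLS_DENSITY_HIGH_THRESHOLD = 5.0   # CLS per 10 cm²


@dataclass(frozen=True)
class CLSCall:
    object_id: int
    annulus_coverage: float
    is_cls: bool


@dataclass(frozen=True)
class CLSDensity:
    n_cls: int
    adipose_area_cm2: float
    cls_per_10cm2: float
    category: str   # "high" (>= 5) | "low" (< 5)


def cd68_positive_mask(
    ihc: np.ndarray,
    dab_threshold: float = 0.15,
    tissue_od_threshold: float = 0.02,
) -> np.ndarray:
    """Binary CD68-positivity mask from an RGB IHC raster.

    Stain separation uses the standard hematoxylin/eosin/DAB
    optical-density vectors; the (non-negative) DAB channel is thresholded
    at ``dab_threshold`` and restricted to tissue (total OD above
    ``tissue_od_threshold``).
    """
    if ihc.ndim != 3 or ihc.shape[2] < 3:
        raise ValueError("cd68_positive_mask expects an RGB raster")
    hed = rgb2hed(ihc)
    dab = np.clip(hed[..., 2], 0.0, None)
    tissue = np.clip(hed, 0.0, None).sum(axis=2) > tissue_od_threshold
    return (dab >= dab_threshold) & tissue


def detect_cls(
    adipocytes: list[AdipocyteObject],
    cd68_mask: np.ndarray,
    microns_per_pixel: float,
    annulus_width_um: float = 20.0,
    coverage_threshold: float = 0.33,
    n_arc_bins: int = 36,
    bin_positive_fraction: float = 0.1,
) -> list[CLSCall]:
    """Score each adipocyte's peri-cellular annulus for CD68 positivity.

    The annulus (pixels within ``annulus_width_um`` outside the contour) is
    split into ``n_arc_bins`` angular bins around the centroid; a bin is
    positive when at least ``bin_positive_fraction`` of its pixels are
    CD68-positive, and coverage is the positive fraction of the occupied
    bins.  ``is_cls`` when coverage >= ``coverage_threshold``.
    """
    h, w = cd68_mask.shape
    calls: list[CLSCall] = []
    for obj in adipocytes:
        poly = Polygon(obj.contour_um)
        outer = poly.buffer(annulus_width_um, quad_segs=16)
        oxy = np.asarray(outer.exterior.coords) / microns_per_pixel
        ixy = obj.contour_um / microns_per_pixel
        ring = np.zeros((h, w), dtype=bool)
        rr, cc = draw_polygon(oxy[:, 1], oxy[:, 0], shape=(h, w))
        ring[rr, cc] = True
        rr, cc = draw_polygon(ixy[:, 1], ixy[:, 0], shape=(h, w))
        ring[rr, cc] = False
        ys, xs = np.nonzero(ring)
        if len(ys) == 0:
            warnings.warn(
                f"object {obj.object_id}: annulus off-canvas, skipped")
            continue
        cx = obj.centroid_xy[0] / microns_per_pixel
        cy = obj.centroid_xy[1] / microns_per_pixel
        ang = np.mod(np.arctan2(ys - cy, xs - cx), 2.0 * np.pi)
        bins = np.minimum((ang / (2.0 * np.pi) * n_arc_bins).astype(int),
                          n_arc_bins - 1)
        pos = cd68_mask[ys, xs]
        tot_per_bin = np.bincount(bins, minlength=n_arc_bins)
        pos_per_bin = np.bincount(bins, weights=pos.astype(float),
                                  minlength=n_arc_bins)
        occupied = tot_per_bin > 0
        frac = np.zeros(n_arc_bins)
        frac[occupied] = pos_per_bin[occupied] / tot_per_bin[occupied]
        coverage = float((frac[occupied] >= bin_positive_fraction).mean())
        calls.append(CLSCall(
            object_id=obj.object_id,
            annulus_coverage=coverage,
            is_cls=coverage >= coverage_threshold,
        ))
    return calls


def cls_density(n_cls: int, adipose_area_cm2: float) -> CLSDensity:
    """CLS per 10 cm² of adipose tissue, dichotomised at >= 5 (high)."""
    if adipose_area_cm2 <= 0:
        raise ValueError("adipose area must be > 0 for a density")
    if n_cls < 0:
        raise ValueError("n_cls must be >= 0")
    dens = 10.0 * n_cls / adipose_area_cm2
    cat = "high" if dens >= CLS_DENSITY_HIGH_THRESHOLD else "low"
    return CLSDensity(n_cls=n_cls, adipose_area_cm2=adipose_area_cm2,
                      cls_per_10cm2=dens, category=cat)


def aggregate_cls(per_slide: list[tuple[int, float]]) -> CLSDensity:
    """Patient-level density: sum counts and areas across a patient's
    sections (multi-block protocols) before dividing."""
    n = sum(c for c, _ in per_slide)
    area = sum(a for _, a in per_slide)
    return cls_density(n, area)
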