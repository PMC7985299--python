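"""Adipocyte segmentation and chord-based morphometry.

Adipocytes are segmented as bright lipid vacuoles on a luminance-thresholded
H&E raster.  Each object is measured through its centroid with 18 chords at
10-degree increments; the per-object size score is the median chord, and the
per-patient size score is the 75th percentile of the kept objects' diameters
and areas.  Objects smaller than 30 µm (median diameter) are excluded to
separate mature adipocytes from debris, and roundness/regularity gates drop
torn or collapsed cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.segmentation import clear_border, watershed

from ._geometry import (CHORD_ANGLES_DEG, chord_lengths, circularity,
                        median_chord, regularity)

__all__ = [
    "CalibratedRaster", "SegmentationParams", "AdipocyteObject",
    "PatientProfile", "NotAssessableError", "segment_vacuoles",
    "measure_object", "qc_filter", "summarize_patient", "measure_image",
]


class NotAssessableError(ValueError):
    """Raised when a patient has no measurable adipocytes."""


@dataclass(frozen=True)
class CalibratedRaster:
    """Image grid plus its spatial calibration (µm per pixel)."""

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self):
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.pixels.size == 0:
            raise ValueError("raster is empty")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and QC gates for vacuole segmentation.

    ``luminance_threshold`` is either the string ``"otsu"`` or a fixed value
    in [0, 1] on the grayscale luminance.  The 30 µm minimum diameter
    separates mature adipocytes from small debris; circularity and
    regularity gates reject torn contours.
    """

    luminance_threshold: str | float = "otsu"
    min_diameter_um: float = 30.0
    min_circularity: float = 0.6
    min_regularity: float = 0.4
    exclude_border: bool = True
    split_touching: bool = False
    duct_exclusion_um: float = 500.0

    def __post_init__(self):
        if not (0.0 <= self.min_circularity <= 1.0):
            raise ValueError("min_circularity must lie in [0, 1]")
        if not (0.0 <= self.min_regularity <= 1.0):
            raise ValueError("min_regularity must lie in [0, 1]")
        if self.min_diameter_um < 0:
            raise ValueError("min_diameter_um must be >= 0")


@dataclass(frozen=True)
class RawObject:
    """A labelled bright region with sub-pixel contour, before measurement."""

    label: int
    contour_um: np.ndarray      # (n, 2) x,y vertices in µm
    n_pixels: int


@dataclass(frozen=True)
class AdipocyteObject:
    """One measured adipocyte (lengths µm, areas µm²)."""

    object_id: int
    centroid_xy: tuple[float, float]
    contour_um: np.ndarray
    area_um2: float
    perimeter_um: float
    chords_um: np.ndarray        # 18 chords at 10-degree increments
    median_diameter_um: float
    circularity: float
    regularity: float
    qc_pass: bool = True
    qc_reason: str = ""


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient morphometry summary at the 75th percentile."""

    patient_id: str
    n_objects_measured: int
    diameter_p75_um: float
    area_p75_um2: float
    mean_area_um2: float
    diameters_um: np.ndarray = field(repr=False, default=None)
    areas_um2: np.ndarray = field(repr=False, default=None)


def _luminance(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 3:
        return rgb2gray(pixels)
    img = pixels.astype(float)
    if img.max() > 1.0:
        img = img / 255.0
    return img


def segment_vacuoles(
    raster: CalibratedRaster,
    params: SegmentationParams = SegmentationParams(),
    roi_mask: np.ndarray | None = None,
    duct_mask: np.ndarray | None = None,
) -> list[RawObject]:
    """Extract candidate vacuole objects from a calibrated raster.

    Bright connected regions are thresholded on luminance, hole-filled,
    optionally watershed-split, cleared at the border, and dropped if they
    overlap the exclusion zone within ``duct_exclusion_um`` of the duct
    mask.  Each surviving region is returned with a sub-pixel iso-contour
    in µm.
    """
    gray = _luminance(raster.pixels)
    mpp = raster.microns_per_pixel
    for mask, name in ((roi_mask, "roi_mask"), (duct_mask, "duct_mask")):
        if mask is not None and mask.shape != gray.shape:
            raise ValueError(f"{name} shape {mask.shape} != raster {gray.shape}")

    if params.luminance_threshold == "otsu":
        if np.ptp(gray) < 1e-12:
            warnings.warn("uniform image: Otsu threshold undefined, no objects")
            return []
        thr = threshold_otsu(gray)
    else:
        thr = float(params.luminance_threshold)
    binary = gray > thr
    if roi_mask is not None:
        binary &= roi_mask.astype(bool)
    binary = ndi.binary_fill_holes(binary)

    # drop specks far below the measurable scale early (10 µm circle)
    min_px = max(4, int(np.pi * (5.0 / mpp) ** 2 / 4))
    if params.exclude_border:
        binary = clear_border(binary)

    if params.split_touching:
        dist = ndi.distance_transform_edt(binary)
        min_dist = max(3, int(params.min_diameter_um / (2 * mpp)))
        peaks = peak_local_max(dist, min_distance=min_dist, labels=binary,
                               exclude_border=False)
        markers = np.zeros_like(binary, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=binary)
    else:
        labels = label(binary)

    if duct_mask is not None:
        zone = ndi.distance_transform_edt(~duct_mask.astype(bool)) * mpp
        excluded = zone < params.duct_exclusion_um
        bad = np.unique(labels[excluded & (labels > 0)])
        if len(bad):
            labels[np.isin(labels, bad)] = 0

    out: list[RawObject] = []
    for rp in regionprops(labels):
        if rp.num_pixels < min_px:
            continue
        # pad so find_contours closes the contour around the region
        sl = rp.slice
        sub = np.pad(labels[sl] == rp.label, 1).astype(float)
        contours = find_contours(sub, 0.5)
        if not contours:
            continue
        cont = max(contours, key=len)
        # (row, col) in padded sub-image -> global pixel coords -> µm
        ys = cont[:, 0] - 1 + sl[0].start
        xs = cont[:, 1] - 1 + sl[1].start
        out.append(RawObject(
            label=rp.label,
            contour_um=np.column_stack([xs, ys]) * mpp,
            n_pixels=int(rp.num_pixels),
        ))
    return out


def measure_object(raw: RawObject, object_id: int | None = None) -> AdipocyteObject:
    """Measure one segmented object: area, perimeter, 18 chords, shape QC.

    The contour is already calibrated, so all outputs are in µm / µm².
    An object whose centroid falls outside its own contour is flagged
    unmeasurable (``qc_reason='unmeasurable'``) and excluded downstream.
    """
    poly = Polygon(raw.contour_um)
    if not poly.is_valid:
        poly = poly.buffer(0)
    oid = raw.label if object_id is None else object_id
    cen = poly.centroid
    area = float(poly.area)
    perim = float(poly.length)
    if area <= 0 or not poly.contains(cen):
        return AdipocyteObject(
            object_id=oid, centroid_xy=(cen.x, cen.y), contour_um=raw.contour_um,
            area_um2=area, perimeter_um=perim,
            chords_um=np.full(len(CHORD_ANGLES_DEG), np.nan),
            median_diameter_um=np.nan, circularity=np.nan, regularity=np.nan,
            qc_pass=False, qc_reason="unmeasurable",
        )
    chords = chord_lengths(poly, center=(cen.x, cen.y))
    return AdipocyteObject(
        object_id=oid, centroid_xy=(cen.x, cen.y), contour_um=raw.contour_um,
        area_um2=area, perimeter_um=perim, chords_um=chords,
        median_diameter_um=median_chord(chords),
        circularity=circularity(area, perim),
        regularity=regularity(chords),
    )


def qc_filter(
    objects: list[AdipocyteObject],
    params: SegmentationParams = SegmentationParams(),
) -> tuple[list[AdipocyteObject], list[AdipocyteObject]]:
    """Split measured objects into kept and rejected-with-reason.

    Rejection reasons (comma-joined when several apply): ``unmeasurable``,
    ``min_diameter`` (median diameter below the 30 µm default),
    ``min_circularity``, ``min_regularity``.
    """
    import dataclasses

    kept, rejected = [], []
    for obj in objects:
        reasons = []
        if obj.qc_reason == "unmeasurable":
            reasons.append("unmeasurable")
        else:
            if obj.median_diameter_um < params.min_diameter_um:
                reasons.append("min_diameter")
            if obj.circularity < params.min_circularity:
                reasons.append("min_circularity")
            if obj.regularity < params.min_regularity:
                reasons.append("min_regularity")
        if reasons:
            rejected.append(dataclasses.replace(
                obj, qc_pass=False, qc_reason=",".join(reasons)))
        else:
            kept.append(dataclasses.replace(obj, qc_pass=True, qc_reason=""))
    return kept, rejected


def summarize_patient(patient_id: str,
                      objects: list[AdipocyteObject]) -> PatientProfile:
    """Per-patient 75th-percentile summary of the kept adipocytes.

    Percentiles use linear interpolation between closest ranks.  Raises
    :class:`NotAssessableError` when no objects survive QC (the slide-level
    analogue of a patient without intact adipose tissue).
    """
    if not objects:
        raise NotAssessableError(
            f"patient {patient_id!r}: no measurable adipocytes")
    diam = np.array([o.median_diameter_um for o in objects])
    area = np.array([o.area_um2 for o in objects])
    return PatientProfile(
        patient_id=patient_id,
        n_objects_measured=len(objects),
        diameter_p75_um=float(np.percentile(diam, 75)),
        area_p75_um2=float(np.percentile(area, 75)),
        mean_area_um2=float(np.mean(area)),
        diameters_um=diam,
        areas_um2=area,
    )


def measure_image(
    raster: CalibratedRaster,
    params: SegmentationParams = SegmentationParams(),
    roi_mask: np.ndarray | None = None,
    duct_mask: np.ndarray | None = None,
) -> tuple[list[AdipocyteObject], list[AdipocyteObject]]:
    """Convenience pipeline: segment, measure, QC-filter one raster."""
    raw = segment_vacuoles(raster, params, roi_mask=roi_mask, duct_mask=duct_mask)
    measured = [measure_object(r, object_id=i) for i, r in enumerate(raw)]
    return qc_filter(measured, params)
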