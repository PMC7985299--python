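"""Chord geometry shared by the synthetic generator and the morphometry module.

The diameter of an adipocyte-like object is summarised from 18 chords drawn
through its centroid at 10-degree increments.  For a non-convex contour a
"chord" is defined as the *total in-object length* of the line through the
centroid at that angle, which reduces to the usual extreme-to-extreme chord
for convex shapes.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point, Polygon

#: the 18 probing angles, degrees
CHORD_ANGLES_DEG = tuple(10.0 * k for k in range(18))


def chord_lengths(
    polygon: Polygon,
    angles_deg=CHORD_ANGLES_DEG,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Length of the in-polygon portion of lines through ``center``.

    Parameters
    ----------
    polygon:
        Closed contour, coordinates in µm (x right, y down).
    angles_deg:
        Probing angles in degrees, measured from the +x axis.
    center:
        Probe point; defaults to the polygon centroid.

    Returns
    -------
    ndarray of chord lengths (µm), one per angle.  A line that misses the
    polygon entirely yields 0.
    """
    if center is None:
        c = polygon.centroid
        cx, cy = c.x, c.y
    else:
        cx, cy = center
    minx, miny, maxx, maxy = polygon.bounds
    # half-length that surely exceeds any chord
    reach = 2.0 * max(maxx - minx, maxy - miny) + 1.0
    out = np.empty(len(angles_deg), dtype=float)
    for i, theta in enumerate(angles_deg):
        t = np.deg2rad(theta)
        dx, dy = np.cos(t), np.sin(t)
        line = LineString(
            [(cx - reach * dx, cy - reach * dy), (cx + reach * dx, cy + reach * dy)]
        )
        out[i] = line.intersection(polygon).length
    return out


def median_chord(chords: np.ndarray) -> float:
    """Median of the chord lengths (mean of the two middle order statistics
    for the even count of 18)."""
    return float(np.median(np.asarray(chords, dtype=float)))


def centroid_inside(polygon: Polygon) -> bool:
    c = polygon.centroid
    return polygon.contains(Point(c.x, c.y))


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric quotient 4πA/P² — 1 for a circle, small for crescents."""
    if perimeter <= 0:
        return 0.0
    return 4.0 * np.pi * area / perimeter**2


def regularity(chords: np.ndarray) -> float:
    """min/max chord ratio — 1 for a circle, low for elongated/torn objects."""
    mx = float(np.max(chords))
    if mx <= 0:
        return 0.0
    return float(np.min(chords)) / mx
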