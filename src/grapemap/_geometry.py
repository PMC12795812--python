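"""Polygon geometry helpers shared by mask processing and morphometrics.

All coordinates follow the raster convention: pixel units, origin at the
top-left corner, y increasing downward, 0-based, polygons living in the
half-open pixel plane.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry


def polygon_moments(poly: Polygon) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and area-covariance matrix of a simple polygon.

    Uses the exact Green's-theorem formulas for the second moments of a
    uniform lamina, so the result is independent of vertex density.

    Returns
    -------
    (area, centroid (2,), covariance (2, 2))
    """
    if poly.is_empty:
        raise ValueError("empty polygon has no moments")
    # use the exterior only after filling holes upstream
    x, y = np.asarray(poly.exterior.coords).T
    x0, y0 = x[:-1], y[:-1]
    x1, y1 = x[1:], y[1:]
    cross = x0 * y1 - x1 * y0
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x0 + x1) * cross).sum() / (6.0 * a)
    cy = ((y0 + y1) * cross).sum() / (6.0 * a)
    # second moments about the origin
    ixx = ((y0**2 + y0 * y1 + y1**2) * cross).sum() / 12.0
    iyy = ((x0**2 + x0 * x1 + x1**2) * cross).sum() / 12.0
    ixy = ((x0 * y1 + 2 * x0 * y0 + 2 * x1 * y1 + x1 * y0) * cross).sum() / 24.0
    area = abs(a)
    sgn = np.sign(a)
    cov = np.array(
        [
            [sgn * iyy / area - cx**2, sgn * ixy / area - cx * cy],
            [sgn * ixy / area - cx * cy, sgn * ixx / area - cy**2],
        ]
    )
    return area, np.array([cx, cy]), cov


def second_moment_axes(poly: Polygon) -> tuple[float, float, float]:
    """Full major/minor axis lengths of the second-moment equivalent ellipse.

    For an ellipse with semi-axes (a, b) the area-covariance eigenvalues are
    (a^2/4, b^2/4), so the full axes are 4*sqrt(eigenvalue) — the same
    definition scikit-image's ``regionprops`` uses for rasters.

    Returns (major_axis, minor_axis, orientation_radians), major >= minor.
    """
    _, _, cov = polygon_moments(poly)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    major = 4.0 * float(np.sqrt(evals[1]))
    minor = 4.0 * float(np.sqrt(evals[0]))
    theta = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    return major, minor, theta


def principal_extent_ratio(points: np.ndarray) -> float:
    """Extent along the first principal axis over the orthogonal extent.

    ``points`` is (n, 2).  Axes come from the eigenvectors of the point
    covariance; extents are peak-to-peak projections.  Always >= 1 (axes are
    ordered by extent, not by eigenvalue, so the ratio cannot dip below 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two points")
    centred = pts - pts.mean(axis=0)
    cov = np.cov(centred.T)
    if np.allclose(cov, 0):
        return 1.0
    _, evecs = np.linalg.eigh(np.atleast_2d(cov))
    proj = centred @ evecs
    extents = np.sort(np.ptp(proj, axis=0))[::-1]
    if extents[-1] <= 0:
        return float("inf")
    return float(extents[0] / extents[1])


def convex_hull_of(geoms: list[BaseGeometry]) -> Polygon:
    """Convex hull of all the geometries' boundary points.

    Identical to the hull of the union but computed directly on the vertex
    set (no polygon union needed).
    """
    from scipy.spatial import ConvexHull, QhullError

    pts = np.vstack([np.asarray(g.exterior.coords)[:-1] for g in geoms])
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate hull (collinear points?): {exc}") from exc
    return Polygon(pts[hull.vertices])


def iou(a: BaseGeometry, b: BaseGeometry) -> float:
    """Intersection-over-union of two geometries (0 when disjoint)."""
    inter = a.intersection(b).area
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)
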