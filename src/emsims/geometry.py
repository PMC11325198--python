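"""Polygon raster/containment primitives shared across the package.

Pixel convention (used everywhere): 0-based indices, the center of pixel
``(row i, col j)`` sits at the point ``(x=j, y=i)``, with the row index
increasing downward. A pixel belongs to a polygon when its center does
(boundary inclusive).
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "as_polygon",
    "shoelace_area",
    "polygon_mask",
    "points_in_polygon",
    "max_pairwise_distance",
]


def as_polygon(vertices) -> Polygon:
    """Build a shapely Polygon from an (n, 2) vertex array."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs an (n>=3, 2) vertex array")
    return Polygon(verts)


def shoelace_area(vertices) -> float:
    """Unsigned shoelace area of a closed vertex sequence (pixel^2)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask under the pixel-center rule.

    Only the polygon's bounding box is scanned, so masks of small objects on
    large grids are cheap.
    """
    poly = vertices if isinstance(vertices, Polygon) else as_polygon(vertices)
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    j0 = max(int(np.floor(minx)), 0)
    j1 = min(int(np.ceil(maxx)), w - 1)
    i0 = max(int(np.floor(miny)), 0)
    i1 = min(int(np.ceil(maxy)), h - 1)
    mask = np.zeros(shape, dtype=bool)
    if j1 < j0 or i1 < i0:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    inside = shapely.intersects_xy(poly, jj.ravel().astype(float), ii.ravel().astype(float))
    mask[i0 : i1 + 1, j0 : j1 + 1] = inside.reshape(ii.shape)
    return mask


def points_in_polygon(points, vertices) -> np.ndarray:
    """Boundary-inclusive point-in-polygon test for an (n, 2) point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return np.zeros(0, dtype=bool)
    poly = vertices if isinstance(vertices, Polygon) else as_polygon(vertices)
    return shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])


def max_pairwise_distance(vertices) -> float:
    """Maximum Euclidean distance between polygon vertices (pixel units).

    The maximum over all vertex pairs equals the maximum over convex-hull
    vertices; the hull reduction keeps hand-drawn, densely sampled outlines
    cheap while remaining exact.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) > 16:
        try:
            from scipy.spatial import ConvexHull

            v = v[ConvexHull(v).vertices]
        except Exception:  # collinear or degenerate input: fall through
            pass
    diff = v[:, None, :] - v[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())
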