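"""Flower diameter and center from convex-polygon morphometry.

The flower outline is summarized by the smallest convex polygon enclosing
its points.  Two quantities are read off it:

* the *diameter* — the maximum pairwise distance between points projected
  onto the plane orthogonal to the flower's main axis (what a caliper
  across the corolla would measure), with the inscribed-circle diameter
  as a configurable alternative;
* the *center* — the Chebyshev center of the polygon, i.e. the in-polygon
  point of maximum distance to the boundary (center of the maximum
  inscribed circle), solved as a linear program over the polygon's
  half-plane constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateHullError, NoDepthError
from .pose3d import FlowerPointCloud, PoseEstimate
from .scene_io import BinaryMask

__all__ = [
    "Polygon2D",
    "convex_hull",
    "chebyshev_center",
    "flower_diameter_mm",
    "center_point_3d",
    "plane_basis",
]

M_TO_MM = 1000.0


@dataclass
class Polygon2D:
    """A strictly convex polygon with counter-clockwise vertices."""

    vertices: np.ndarray  # (K, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def convex_hull(points) -> Polygon2D:
    """Smallest convex polygon enclosing a planar point set.

    Vertices are returned counter-clockwise with duplicate and collinear
    vertices pruned.  Raises :class:`DegenerateHullError` for fewer than
    3 points or an all-collinear set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be N x 2")
    if len(pts) < 3:
        raise DegenerateHullError(f"degenerate hull: {len(pts)} point(s)")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(f"degenerate hull: {exc}") from exc
    return Polygon2D(vertices=pts[hull.vertices])  # qhull: CCW, extreme points only


def chebyshev_center(poly: Polygon2D) -> tuple[tuple[float, float], float]:
    """Center and radius of the polygon's maximum inscribed circle.

    Maximize r subject to aᵢ·x + r‖aᵢ‖ ≤ bᵢ over the polygon's edge
    half-planes; for a convex polygon the LP optimum is the Chebyshev
    center (reported even when the optimal set is a segment under ties).
    """
    v = poly.vertices
    nxt = np.roll(v, -1, axis=0)
    edges = nxt - v
    # outward normals of a CCW polygon: rotate edge by -90 degrees
    normals = np.column_stack([edges[:, 1], -edges[:, 0]])
    norms = np.linalg.norm(normals, axis=1)
    b = np.einsum("ij,ij->i", normals, v)
    # variables (x, y, r): minimize -r
    a_ub = np.column_stack([normals, norms])
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=a_ub,
        b_ub=b,
        bounds=[(None, None), (None, None), (0.0, None)],
        method="highs",
    )
    if not res.success:  # pragma: no cover - cannot happen for a valid polygon
        raise RuntimeError(f"Chebyshev LP failed: {res.message}")
    x, y, r = res.x
    return (float(x), float(y)), float(r)


def plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal vectors spanning the plane orthogonal to ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b1 = np.cross(axis, helper)
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    return b1, b2


def flower_diameter_mm(
    cloud: FlowerPointCloud,
    pose: PoseEstimate,
    method: str = "max_caliper",
) -> float:
    """Flower diameter in mm, measured in the flower's own plane.

    Points are projected onto the plane orthogonal to ``pose.main_axis``
    through the centroid.  ``max_caliper`` (default) reports the maximum
    pairwise distance, computed over the convex-hull vertices (rotating-
    calipers width); ``inscribed`` reports twice the Chebyshev radius of
    the hull.  When the projected points are collinear the max pairwise
    distance is still well defined and is returned for ``max_caliper``.
    """
    if method not in ("max_caliper", "inscribed"):
        raise ValueError(f"unknown diameter method {method!r}")
    b1, b2 = plane_basis(pose.main_axis)
    centered = cloud.points - pose.centroid
    proj = np.column_stack([centered @ b1, centered @ b2])
    try:
        poly = convex_hull(proj)
    except DegenerateHullError:
        if method == "inscribed":
            raise
        uniq = np.unique(proj, axis=0)
        if len(uniq) < 2:
            raise DegenerateHullError("degenerate hull: fewer than 2 distinct points")
        return float(_max_pairwise(uniq) * M_TO_MM)
    if method == "inscribed":
        _, radius = chebyshev_center(poly)
        return float(2.0 * radius * M_TO_MM)
    return float(_max_pairwise(poly.vertices) * M_TO_MM)


def _max_pairwise(pts: np.ndarray) -> float:
    diffs = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diffs ** 2).sum(axis=2)).max())


def center_point_3d(
    cloud: FlowerPointCloud,
    mask: BinaryMask,
    top_fraction: float = 0.1,
    max_center_gap_px: float = 10.0,
) -> tuple[tuple[float, float], np.ndarray]:
    """Flower center as a (sub-)pixel location and a 3D point.

    The pixel center is the Chebyshev center of the convex hull of the
    mask's true pixels.  The 3D center lies on the ray through that pixel:
    the nearest cloud point supplies the ray, and its depth is replaced by
    the mean z of the top ``top_fraction`` (smallest-z) flower points —
    the camera-facing top of the flower, robust to single-pixel outliers.

    Raises :class:`NoDepthError` when no finite point lies within
    ``max_center_gap_px`` of the center pixel.
    """
    rows, cols = np.nonzero(mask.grid)
    if rows.size == 0:
        raise NoDepthError("empty mask")
    pix = np.column_stack([cols, rows]).astype(float)  # (u, v)
    try:
        poly = convex_hull(pix)
        (cu, cv), _ = chebyshev_center(poly)
    except DegenerateHullError:
        cu, cv = pix.mean(axis=0)
    d2 = (cloud.source_pixels[:, 0] - cu) ** 2 + (cloud.source_pixels[:, 1] - cv) ** 2
    nearest = int(np.argmin(d2))
    if d2[nearest] > max_center_gap_px ** 2:
        raise NoDepthError(
            f"no finite depth within {max_center_gap_px} px of center pixel "
            f"({cu:.1f}, {cv:.1f})"
        )
    z = cloud.points[:, 2]
    k = max(1, int(np.ceil(top_fraction * len(z))))
    z_top = float(np.sort(z)[:k].mean())
    anchor = cloud.points[nearest]
    # the anchor lies on the pixel ray; rescale it to the top depth
    center = anchor * (z_top / anchor[2])
    return (float(cu), float(cv)), center
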