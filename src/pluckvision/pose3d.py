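"""Flower pose estimation: mask-isolated point clouds and PCA axes.

The cleaned 2D segmentation mask selects, pixel for pixel, the 3D points
of one flower out of the organized cloud.  Principal component analysis
of those points yields three orthonormal axes ordered by variance.  For a
disk- or dome-shaped flower face the surface normal — the direction the
stem extends — is the *minimum*-variance eigenvector, so the main axis
defaults to ``e3``; ``max_variance`` selects ``e1`` for elongated targets.

The main axis is sign-normalized to a non-negative Z component: with a
downward-looking camera (+Z into the canopy) it points stem-ward, the
direction the flower center is translated to reach the plucking point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDepthError
from .scene_io import BinaryMask, Frame

__all__ = ["FlowerPointCloud", "PoseEstimate", "isolate_points", "pca_pose", "angular_error"]

#: eigenvalue ratio below which the cloud is treated as rank-deficient
_RANK_RTOL = 1e-12


@dataclass
class FlowerPointCloud:
    """Finite 3D points of one flower plus their source pixels.

    points : (N, 3) float array, meters, camera frame.
    source_pixels : (N, 2) int array of (u, v) pixel coordinates.
    n_dropped : number of masked pixels discarded for invalid depth.
    """

    points: np.ndarray
    source_pixels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.source_pixels = np.asarray(self.source_pixels)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be N x 3")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("flower point cloud must be all finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class PoseEstimate:
    """PCA axes of a flower cloud.

    ``e1, e2, e3`` are orthonormal eigenvectors of the point covariance
    with eigenvalues λ1 ≥ λ2 ≥ λ3 ≥ 0; ``main_axis`` is the oriented copy
    of the axis chosen by the main-axis rule, with main_axis·ẑ ≥ 0.
    """

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray
    eigenvalues: tuple[float, float, float]
    main_axis: np.ndarray
    centroid: np.ndarray


def isolate_points(frame: Frame, mask: BinaryMask, min_points: int = 3) -> FlowerPointCloud:
    """Extract the finite cloud points under a mask's true pixels.

    NaN (invalid-depth) points are dropped and counted, never filled in.
    Raises :class:`InsufficientDepthError` when fewer than ``min_points``
    finite points remain.
    """
    if mask.shape != frame.shape:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frame.shape}")
    rows, cols = np.nonzero(mask.grid)
    pts = frame.cloud[rows, cols]
    finite = np.isfinite(pts[:, 2])
    n_finite = int(finite.sum())
    if n_finite < min_points:
        raise InsufficientDepthError(n_finite, min_points)
    return FlowerPointCloud(
        points=pts[finite],
        source_pixels=np.column_stack([cols[finite], rows[finite]]),
        n_dropped=int((~finite).sum()),
    )


def pca_pose(cloud: FlowerPointCloud, main_axis_rule: str = "min_variance") -> PoseEstimate:
    """Estimate a flower's pose by PCA of its point cloud.

    Eigen-decomposition of the 3x3 covariance of the mean-centered points
    (the reference formulation; SVD of the centered data matrix agrees and
    is asserted in tests).  Raises :class:`DegenerateGeometryError` when
    the covariance has two (near-)zero eigenvalues, i.e. the points are
    collinear and the minor axes are undefined.
    """
    if main_axis_rule not in ("min_variance", "max_variance"):
        raise ValueError(f"unknown main_axis_rule {main_axis_rule!r}")
    pts = cloud.points
    if len(pts) < 3:
        raise InsufficientDepthError(len(pts), 3)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    axes = evecs[:, order].T  # rows e1, e2, e3
    if evals[1] <= _RANK_RTOL * max(evals[0], 1e-300) or evals[0] == 0.0:
        raise DegenerateGeometryError(
            "degenerate geometry: points are collinear or coincident"
        )
    main = axes[2] if main_axis_rule == "min_variance" else axes[0]
    main = _orient_positive_z(main)
    return PoseEstimate(
        e1=axes[0],
        e2=axes[1],
        e3=axes[2],
        eigenvalues=(float(evals[0]), float(evals[1]), float(evals[2])),
        main_axis=main,
        centroid=centroid,
    )


def _orient_positive_z(u: np.ndarray) -> np.ndarray:
    """Flip a unit vector so its Z component is non-negative.

    When the vector is exactly horizontal (z == 0), orient the first
    nonzero component positive for a deterministic sign.
    """
    if u[2] < 0:
        return -u
    if u[2] == 0:
        for comp in u:
            if comp != 0:
                return u if comp > 0 else -u
    return u


def angular_error(u: np.ndarray, v: np.ndarray, atol: float = 1e-6) -> float:
    """Sign-agnostic angle between two unit 3-vectors, in degrees [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > atol or abs(np.linalg.norm(v) - 1.0) > atol:
        raise ValueError("angular_error expects unit vectors")
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), 0.0, 1.0))))
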