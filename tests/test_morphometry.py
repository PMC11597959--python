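"""Convex hull, Chebyshev center (vs brute force and shapely), diameter."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, Polygon as ShapelyPolygon

from pluckvision.errors import DegenerateHullError, NoDepthError
from pluckvision.morphometry import (
    Polygon2D,
    center_point_3d,
    chebyshev_center,
    convex_hull,
    flower_diameter_mm,
)
from pluckvision.pose3d import FlowerPointCloud, pca_pose
from pluckvision.scene_io import BinaryMask
from tests.test_pose3d import cloud_of, disk_points


def _grid_scan(sp, x0, x1, y0, y1, pitch):
    xs = np.arange(x0, x1 + pitch, pitch)
    ys = np.arange(y0, y1 + pitch, pitch)
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())
    inside = shapely.contains(sp, pts)
    if not inside.any():
        return None, -1.0
    d = shapely.distance(sp.exterior, pts[inside])
    k = int(np.argmax(d))
    xi = xx.ravel()[inside][k]
    yi = yy.ravel()[inside][k]
    return (float(xi), float(yi)), float(d[k])


def grid_chebyshev(poly: Polygon2D, pitch=1e-3):
    """Brute-force maximizer of boundary distance on a dense grid.

    Coarse scan over the bounding box, then a fine scan at ``pitch``
    around the coarse maximizer (still an exhaustive grid search).
    """
    sp = ShapelyPolygon(poly.vertices)
    x0, y0, x1, y1 = sp.bounds
    coarse = max(pitch, (x1 - x0) / 120.0)
    (cx, cy), _ = _grid_scan(sp, x0, x1, y0, y1, coarse)
    w = 3 * coarse
    return _grid_scan(sp, cx - w, cx + w, cy - w, cy + w, pitch)


def random_convex_polygon(rng, n=12, scale=1.0):
    """Convex hull of random points in a disk (>= 3 vertices)."""
    pts = rng.normal(size=(n, 2)) * scale
    return convex_hull(pts)


class TestConvexHull:
    def test_unit_square_plus_center(self):
        pts = [(0, 0), (1, 0), (1, 1), (0, 1), (0.5, 0.5)]
        poly = convex_hull(pts)
        assert len(poly.vertices) == 4
        assert poly.area == pytest.approx(1.0)

    def test_all_points_inside_hull(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(100, 2))
        poly = convex_hull(pts)
        sp = ShapelyPolygon(poly.vertices).buffer(1e-9)
        assert all(sp.contains(Point(p)) for p in pts)

    def test_ccw_orientation(self):
        poly = convex_hull(np.random.default_rng(3).normal(size=(30, 2)))
        x, y = poly.vertices[:, 0], poly.vertices[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0

    def test_collinear_degenerate(self):
        with pytest.raises(DegenerateHullError):
            convex_hull([(0, 0), (1, 1), (2, 2)])

    def test_too_few_points(self):
        with pytest.raises(DegenerateHullError):
            convex_hull([(0, 0), (1, 1)])


class TestChebyshevCenter:
    def test_unit_square(self):
        poly = Polygon2D(vertices=np.array([(0, 0), (1, 0), (1, 1), (0, 1)], float))
        (cx, cy), r = chebyshev_center(poly)
        assert (cx, cy) == pytest.approx((0.5, 0.5), abs=1e-9)
        assert r == pytest.approx(0.5, abs=1e-9)

    def test_345_right_triangle_incircle(self):
        poly = Polygon2D(vertices=np.array([(0, 0), (4, 0), (0, 3)], float))
        (cx, cy), r = chebyshev_center(poly)
        assert r == pytest.approx(1.0, abs=1e-9)  # (3 + 4 - 5) / 2
        assert (cx, cy) == pytest.approx((1.0, 1.0), abs=1e-9)

    def test_irregular_pentagon_matches_grid_search(self):
        poly = Polygon2D(
            vertices=np.array([(0, 0), (2.2, -0.4), (3.1, 1.2), (1.5, 2.6), (-0.3, 1.4)])
        )
        (gx, gy), gr = grid_chebyshev(poly, pitch=1e-3)
        (cx, cy), r = chebyshev_center(poly)
        assert abs(r - gr) <= 2e-3  # within grid pitch
        assert np.hypot(cx - gx, cy - gy) <= 5e-3

    def test_random_polygons_match_shapely_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            poly = random_convex_polygon(rng)
            (cx, cy), r = chebyshev_center(poly)
            circle = shapely.maximum_inscribed_circle(
                ShapelyPolygon(poly.vertices), tolerance=1e-7
            )
            r_ref = circle.length  # LineString center->boundary: length = radius
            assert r == pytest.approx(r_ref, abs=1e-4)
            sp = ShapelyPolygon(poly.vertices)
            assert sp.contains(Point(cx, cy))  # strictly inside
            circumradius = np.max(
                np.hypot(poly.vertices[:, 0] - cx, poly.vertices[:, 1] - cy)
            )
            assert r <= circumradius


class TestFlowerDiameter:
    def _circle_cloud(self, radius_m, z0=0.5, n=120):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack(
            [radius_m * np.cos(th), radius_m * np.sin(th), np.full(n, z0)]
        )
        return cloud_of(pts)

    def test_circle_36mm(self):
        cloud = self._circle_cloud(0.018)
        pose = pca_pose(cloud)
        assert flower_diameter_mm(cloud, pose) == pytest.approx(36.0, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        cloud = self._circle_cloud(0.018, z0=0.0)
        th = np.radians(30)
        rot_x = np.array(
            [[1, 0, 0], [0, np.cos(th), -np.sin(th)], [0, np.sin(th), np.cos(th)]]
        )
        pts = cloud.points @ rot_x.T + [0, 0, 0.5]
        rotated = cloud_of(pts)
        d0 = flower_diameter_mm(cloud_of(cloud.points + [0, 0, 0.5]), pca_pose(cloud_of(cloud.points + [0, 0, 0.5])))
        d1 = flower_diameter_mm(rotated, pca_pose(rotated))
        assert d1 == pytest.approx(36.0, rel=1e-6)
        assert d1 == pytest.approx(d0, rel=1e-6)

    def test_two_distinct_points_plus_duplicate(self):
        pts = np.array([[0, 0, 0.5], [0.01, 0, 0.5], [0.01, 0, 0.5], [0.005, 0, 0.5]])
        cloud = cloud_of(pts)

        class FlatPose:
            main_axis = np.array([0, 0, 1.0])
            centroid = pts.mean(axis=0)

        assert flower_diameter_mm(cloud, FlatPose()) == pytest.approx(10.0, abs=1e-9)

    def test_noisy_disk_recovery_2mm(self):
        # |estimate - d*| <= 2 mm at sigma = 1 mm depth noise, N >= 300
        rng = np.random.default_rng(17)
        for d_true in (28.0, 36.0, 60.0):
            pts = disk_points(500, d_true / 2000.0, rng=rng, depth_noise_sd_m=0.001)
            cloud = cloud_of(pts)
            est = flower_diameter_mm(cloud, pca_pose(cloud))
            assert abs(est - d_true) <= 2.0

    def test_diameter_at_least_inscribed(self):
        rng = np.random.default_rng(19)
        pts = disk_points(400, 0.02, rng=rng)
        cloud = cloud_of(pts)
        pose = pca_pose(cloud)
        d_max = flower_diameter_mm(cloud, pose, method="max_caliper")
        d_insc = flower_diameter_mm(cloud, pose, method="inscribed")
        assert d_max >= d_insc > 0


class TestCenterPoint3D:
    def _disk_setup(self, h=80, w=100, cv=40, cu=50, radius=20, z_profile=None):
        vv, uu = np.mgrid[0:h, 0:w]
        grid = (uu - cu) ** 2 + (vv - cv) ** 2 <= radius ** 2
        rows, cols = np.nonzero(grid)
        scale = 0.0005  # m per pixel at this depth
        if z_profile is None:
            z = np.full(rows.size, 0.5)
        else:
            z = z_profile(rows, cols)
        pts = np.column_stack([(cols - cu) * scale, (rows - cv) * scale, z])
        cloud = FlowerPointCloud(points=pts, source_pixels=np.column_stack([cols, rows]))
        return cloud, BinaryMask(grid=grid)

    def test_pixel_center_at_disk_center(self):
        cloud, mask = self._disk_setup()
        (cu, cv), _ = center_point_3d(cloud, mask)
        assert np.hypot(cu - 50, cv - 40) < 1.0

    def test_flat_flower_z(self):
        cloud, mask = self._disk_setup()
        _, center = center_point_3d(cloud, mask)
        assert center[2] == pytest.approx(0.5, abs=1e-9)

    def test_dome_top_decile_z(self):
        # apex z = 0.48 at the center, rim z = 0.50
        def profile(rows, cols):
            r = np.hypot(cols - 50, rows - 40)
            return 0.48 + 0.02 * (r / 20.0) ** 2

        cloud, mask = self._disk_setup(z_profile=profile)
        _, center = center_point_3d(cloud, mask)
        # independent oracle: mean of the lowest-z decile of the same points
        z = np.sort(cloud.points[:, 2])
        expected = z[: int(np.ceil(0.1 * z.size))].mean()
        assert center[2] == pytest.approx(expected, abs=1e-12)
        assert 0.48 <= center[2] <= 0.482

    def test_no_depth_near_center(self):
        cloud, mask = self._disk_setup()
        # keep only points far from the center pixel
        far = np.hypot(
            cloud.source_pixels[:, 0] - 50, cloud.source_pixels[:, 1] - 40
        ) > 15
        trimmed = FlowerPointCloud(
            points=cloud.points[far], source_pixels=cloud.source_pixels[far]
        )
        with pytest.raises(NoDepthError):
            center_point_3d(trimmed, mask, max_center_gap_px=5.0)
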