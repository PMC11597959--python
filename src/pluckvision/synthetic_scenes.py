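"""Synthetic flowers, frames and measurement tables with ground truth.

Everything downstream of the deep detectors is pure geometry, so it can
be exercised on simulated data: flowers are spherical caps (a disk when
the dome height is zero) of known diameter, pose and plucking height,
imaged by a pinhole camera looking down at a bench.  Rendering is exact
ray casting — every rendered cloud point lies on its pixel's ray — so
projection round-trips are lossless and the only errors a test measures
are the estimators' own.

The generator's defaults mirror the study conditions: a 1280×720
organized cloud (921,600 points), a bench ≈ 0.5 m from the camera,
species diameters around 28 mm (snapdragon), 36 mm (marigold) and up to
60 mm (pansy, right-tailed two-component mixture), and measurement
tables of 300 flowers evenly split across the three species whose h(d)
lines default to the packaged calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .pose3d import FlowerPointCloud
from .scene_io import (
    BinaryMask,
    Detection,
    Frame,
    Measurement,
    write_mask,
    write_measurements,
    write_organized_ply,
)

__all__ = [
    "SyntheticFlower",
    "CameraModel",
    "make_flower_cloud",
    "render_scene",
    "make_measurements",
    "sample_flowers",
    "write_scene",
    "DEFAULT_SPECIES_PARAMS",
]

#: species color used to paint the RGB image (RGB, uint8)
SPECIES_COLORS = {
    "marigold": (255, 140, 0),
    "snapdragon": (225, 210, 40),
    "pansy": (150, 60, 180),
}
BACKGROUND_COLOR = (40, 120, 40)

#: measurement-generator defaults: slope, intercept (mm), residual sd (mm),
#: diameter range (mm).  Slopes/intercepts are the packaged calibration
#: lines; the residual sd and ranges are chosen to be caliper-realistic.
DEFAULT_SPECIES_PARAMS = {
    "pansy": {"a": 0.36, "b": 26.33, "sigma_mm": 8.0, "d_range_mm": (20.0, 60.0),
              "mixture": ((20.0, 40.0), (40.0, 60.0), 0.7)},
    "snapdragon": {"a": 0.38, "b": 5.33, "sigma_mm": 8.0, "d_range_mm": (18.0, 38.0)},
    "marigold": {"a": 0.66, "b": 7.10, "sigma_mm": 8.0, "d_range_mm": (26.0, 46.0)},
}


@dataclass
class CameraModel:
    """Pinhole camera: u = f·x/z + cx, v = f·y/z + cy (pixels)."""

    width: int = 1280
    height: int = 720
    focal_px: float = 700.0
    cx: float | None = None
    cy: float | None = None

    def __post_init__(self) -> None:
        if self.cx is None:
            self.cx = (self.width - 1) / 2.0
        if self.cy is None:
            self.cy = (self.height - 1) / 2.0
        if self.focal_px <= 0:
            raise ValueError("focal length must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def project(self, points: np.ndarray) -> np.ndarray:
        """(N, 3) points -> (N, 2) pixel (u, v)."""
        p = np.asarray(points, dtype=float)
        return np.column_stack(
            [self.focal_px * p[:, 0] / p[:, 2] + self.cx,
             self.focal_px * p[:, 1] / p[:, 2] + self.cy]
        )

    def ray(self, u, v) -> np.ndarray:
        """Unit-z ray direction(s) through pixel center(s) (u, v)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return np.stack(
            [(u - self.cx) / self.focal_px, (v - self.cy) / self.focal_px, np.ones_like(u)],
            axis=-1,
        )


@dataclass
class SyntheticFlower:
    """Ground-truth flower: a spherical cap of known pose and size.

    ``center_3d`` is the cap apex (the camera-facing top of the flower);
    ``main_axis`` points stem-ward (+Z-leaning); the true plucking point
    is exactly ``center_3d + (true_h_mm/1000)·main_axis``.
    """

    species: str
    center_3d: np.ndarray
    main_axis: np.ndarray
    diameter_mm: float
    dome_height_mm: float
    true_h_mm: float

    def __post_init__(self) -> None:
        self.center_3d = np.asarray(self.center_3d, dtype=float)
        axis = np.asarray(self.main_axis, dtype=float)
        self.main_axis = axis / np.linalg.norm(axis)
        if self.main_axis[2] < 0:
            raise ValueError("main_axis must be +Z-leaning")
        if self.diameter_mm <= 0 or self.dome_height_mm < 0 or self.true_h_mm < 0:
            raise ValueError("diameter, dome height and h must be non-negative")

    @property
    def true_pluck_point(self) -> np.ndarray:
        return self.center_3d + (self.true_h_mm / 1000.0) * self.main_axis


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +Z to ``axis`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    axis = axis / np.linalg.norm(axis)
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    s = np.linalg.norm(v)
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _cap_sphere_radius(radius_m: float, dome_m: float) -> float:
    """Radius of the sphere whose cap has base radius R and height hd."""
    return (radius_m ** 2 + dome_m ** 2) / (2.0 * dome_m)


def make_flower_cloud(
    flower: SyntheticFlower,
    n_points: int = 500,
    noise_sd_mm: float = 0.0,
    seed: int = 0,
) -> FlowerPointCloud:
    """Sample a flower's surface as a point cloud (seeded, reproducible).

    Points are drawn uniformly over the cap's base disk; the surface is a
    spherical cap (flat disk for dome height 0) with its apex at the
    flower center and its normal along the main axis.  ``noise_sd_mm`` is
    Gaussian *depth* noise applied along the camera z axis — the error an
    RGB-D stereo sensor makes; lateral position comes from the pixel grid
    and is comparatively exact.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = np.random.default_rng(seed)
    radius = flower.diameter_mm / 2000.0  # m
    dome = flower.dome_height_mm / 1000.0
    r = radius * np.sqrt(rng.random(n_points))
    theta = rng.random(n_points) * 2.0 * np.pi
    x, y = r * np.cos(theta), r * np.sin(theta)
    if dome > 0:
        rs = _cap_sphere_radius(radius, dome)
        z = rs - np.sqrt(rs ** 2 - r ** 2)  # apex 0 -> rim = dome
    else:
        z = np.zeros(n_points)
    local = np.column_stack([x, y, z])
    rot = _rotation_to(flower.main_axis)
    pts = local @ rot.T + flower.center_3d
    if noise_sd_mm > 0:
        pts[:, 2] += rng.normal(0.0, noise_sd_mm / 1000.0, n_points)
    pix = np.zeros((n_points, 2), dtype=int)  # no camera attached here
    return FlowerPointCloud(points=pts, source_pixels=pix)


def _intersect_cap(
    rays: np.ndarray, flower: SyntheticFlower, rot: np.ndarray
) -> np.ndarray:
    """Depth t (camera z) where each pixel ray hits the cap, NaN if missed.

    ``rays`` are (N, 3) unit-z directions; the ray is p(t) = t·ray with
    origin at the camera.  Everything is solved in the flower's local
    frame (apex at origin, +z along the main axis).
    """
    radius = flower.diameter_mm / 2000.0
    dome = flower.dome_height_mm / 1000.0
    o_local = -rot.T @ flower.center_3d  # ray origin in local frame
    d_local = rays @ rot  # (N, 3) directions in local frame
    t = np.full(len(rays), np.nan)
    if dome <= 1e-9:
        dz = d_local[:, 2]
        ok = np.abs(dz) > 1e-15
        tt = np.where(ok, -o_local[2] / np.where(ok, dz, 1.0), np.nan)
        hit = o_local[None, :] + tt[:, None] * d_local
        r2 = hit[:, 0] ** 2 + hit[:, 1] ** 2
        good = ok & (tt > 0) & (r2 <= radius ** 2)
        t[good] = tt[good]
        return t
    rs = _cap_sphere_radius(radius, dome)
    s = np.array([0.0, 0.0, rs])  # sphere center in local frame
    oc = o_local - s
    a = np.einsum("ij,ij->i", d_local, d_local)
    b = 2.0 * d_local @ oc
    c = float(oc @ oc) - rs ** 2
    disc = b ** 2 - 4 * a * c
    has = disc >= 0
    sq = np.sqrt(np.where(has, disc, 0.0))
    for root in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        hit = o_local[None, :] + root[:, None] * d_local
        good = has & (root > 0) & (hit[:, 2] <= dome + 1e-12) & np.isnan(t)
        t[good] = root[good]
    return t


def render_scene(
    flowers: Sequence[SyntheticFlower],
    camera: CameraModel | None = None,
    background_depth_m: float = 0.5,
    seed: int = 0,
    noise_sd_mm: float = 0.0,
) -> tuple[Frame, list[Detection], list[BinaryMask], dict]:
    """Render flowers into an organized RGB-D frame with ground truth.

    Returns ``(frame, detections, masks, ground_truth)``.  Each pixel's
    cloud point lies exactly on that pixel's ray (z-buffered across
    flowers, nearest wins; the background plane fills the rest), so the
    deeper flower of an overlapping pair loses the shared pixels.  Depth
    noise, when requested, perturbs z along the ray, preserving the
    projection round-trip.  Masks/detections are emitted per flower with
    at least one visible pixel, in input order.
    """
    camera = camera or CameraModel()
    if background_depth_m < 0:
        raise ValueError("background depth must be non-negative")
    for fl in flowers:
        if fl.center_3d[2] <= 0:
            raise ValueError("flowers must lie in front of the camera")
    h, w = camera.height, camera.width
    zbuf = np.full((h, w), np.inf)
    owner = np.full((h, w), -1, dtype=int)
    rng = np.random.default_rng(seed)

    for k, fl in enumerate(flowers):
        rot = _rotation_to(fl.main_axis)
        # pixel bbox: project apex + rim circle, pad by 2 px
        ang = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
        radius = fl.diameter_mm / 2000.0
        dome = fl.dome_height_mm / 1000.0
        rim_local = np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.full(64, dome)]
        )
        boundary = np.vstack([rim_local @ rot.T + fl.center_3d, fl.center_3d])
        uv = camera.project(boundary)
        u0 = max(0, int(np.floor(uv[:, 0].min())) - 2)
        u1 = min(w - 1, int(np.ceil(uv[:, 0].max())) + 2)
        v0 = max(0, int(np.floor(uv[:, 1].min())) - 2)
        v1 = min(h - 1, int(np.ceil(uv[:, 1].max())) + 2)
        if u1 < u0 or v1 < v0:
            continue
        uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        rays = camera.ray(uu.ravel(), vv.ravel())
        t = _intersect_cap(rays, fl, rot)
        hit = np.isfinite(t)
        rr, cc = vv.ravel()[hit], uu.ravel()[hit]
        tz = t[hit]  # unit-z rays: t equals camera depth z
        closer = tz < zbuf[rr, cc]
        zbuf[rr[closer], cc[closer]] = tz[closer]
        owner[rr[closer], cc[closer]] = k

    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = BACKGROUND_COLOR
    cloud = np.empty((h, w, 3))
    uu, vv = np.meshgrid(np.arange(w), np.arange(h))
    rays = camera.ray(uu, vv)
    cloud[:] = rays * background_depth_m

    masks: list[BinaryMask] = []
    detections: list[Detection] = []
    gt_records = []
    for k, fl in enumerate(flowers):
        vis = owner == k
        n_vis = int(vis.sum())
        if n_vis:
            z = zbuf[vis]
            if noise_sd_mm > 0:
                z = z + rng.normal(0.0, noise_sd_mm / 1000.0, z.shape)
            cloud[vis] = rays[vis] * z[:, None]
            image[vis] = SPECIES_COLORS.get(fl.species, (255, 140, 0))
            rows, cols = np.nonzero(vis)
            detections.append(
                Detection(
                    bbox=(float(cols.min()), float(rows.min()),
                          float(cols.max() + 1), float(rows.max() + 1)),
                    label=fl.species,
                    confidence=1.0,
                )
            )
            masks.append(BinaryMask(grid=vis, provenance="external"))
        gt_records.append(
            {
                "species": fl.species,
                "center_3d": fl.center_3d.tolist(),
                "main_axis": fl.main_axis.tolist(),
                "diameter_mm": fl.diameter_mm,
                "dome_height_mm": fl.dome_height_mm,
                "true_h_mm": fl.true_h_mm,
                "true_pluck_point": fl.true_pluck_point.tolist(),
                "visible_px": n_vis,
            }
        )
    frame = Frame(image=image, cloud=cloud, frame_id="synthetic")
    ground_truth = {
        "camera": {"width": w, "height": h, "focal_px": camera.focal_px,
                   "cx": camera.cx, "cy": camera.cy},
        "background_depth_m": background_depth_m,
        "noise_sd_mm": noise_sd_mm,
        "flowers": gt_records,
    }
    return frame, detections, masks, ground_truth


def sample_flowers(
    n_flowers: int,
    seed: int = 0,
    species: Sequence[str] = ("marigold", "snapdragon", "pansy"),
    bench_depth_m: float = 0.5,
    tilt_max_deg: float = 15.0,
    dome_height_mm: float = 3.0,
    h_rule: Callable[[str, float], float] | None = None,
    camera: CameraModel | None = None,
) -> list[SyntheticFlower]:
    """Draw a random, non-overlapping arrangement of flowers on the bench.

    Flowers are placed on a jittered grid so footprints stay disjoint;
    species cycle through ``species``; diameters are drawn from each
    species' default range; tilts are uniform in [0, tilt_max_deg].
    ``h_rule(species, d_mm)`` supplies the true plucking height; by
    default it is the packaged upper-boundary line of the species.
    """
    from .pluck_calibration import load_packaged_coefficients, predict_h

    camera = camera or CameraModel()
    rng = np.random.default_rng(seed)
    if h_rule is None:
        lines = {sp: load_packaged_coefficients(sp)[1] for sp in set(species)}
        h_rule = lambda sp, d: predict_h(lines[sp], d)  # noqa: E731

    # grid of candidate positions, spaced so 60 mm flowers cannot touch
    spacing_m = 0.12
    nx = int((camera.width - 150) / camera.focal_px * bench_depth_m / spacing_m) + 1
    ny = int((camera.height - 150) / camera.focal_px * bench_depth_m / spacing_m) + 1
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing_m
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing_m
    grid = [(x, y) for y in ys for x in xs]
    if n_flowers > len(grid):
        raise ValueError(f"at most {len(grid)} flowers fit without overlap")
    slots = rng.choice(len(grid), size=n_flowers, replace=False)

    flowers = []
    for i, slot in enumerate(slots):
        sp = species[i % len(species)]
        lo, hi = DEFAULT_SPECIES_PARAMS[sp]["d_range_mm"]
        d = float(rng.uniform(lo, hi))
        tilt = np.radians(rng.uniform(0.0, tilt_max_deg))
        phi = rng.uniform(0.0, 2 * np.pi)
        axis = np.array(
            [np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)]
        )
        gx, gy = grid[slot]
        jitter = rng.uniform(-0.015, 0.015, 2)
        center = np.array([gx + jitter[0], gy + jitter[1],
                           bench_depth_m + float(rng.uniform(-0.01, 0.01))])
        flowers.append(
            SyntheticFlower(
                species=sp,
                center_3d=center,
                main_axis=axis,
                diameter_mm=d,
                dome_height_mm=dome_height_mm,
                true_h_mm=float(h_rule(sp, d)),
            )
        )
    return flowers


def make_measurements(
    species_params: dict | None = None,
    n_per_species: int = 100,
    seed: int = 0,
) -> list[Measurement]:
    """Generate a caliper-style measurement table, seeded.

    For each species, diameters are uniform in its range (pansy uses a
    right-tailed two-component mixture by default) and heights follow
    ``h = a·d + b + N(0, sigma)``; any non-positive h draw is redrawn at
    the linear mean (only reachable with extreme sigma).
    """
    params = species_params or DEFAULT_SPECIES_PARAMS
    rng = np.random.default_rng(seed)
    out: list[Measurement] = []
    for sp in params:
        p = params[sp]
        a, b, sigma = p["a"], p["b"], p["sigma_mm"]
        mix = p.get("mixture")
        if mix is not None:
            (lo1, hi1), (lo2, hi2), w1 = mix
            pick = rng.random(n_per_species) < w1
            d = np.where(
                pick, rng.uniform(lo1, hi1, n_per_species), rng.uniform(lo2, hi2, n_per_species)
            )
        else:
            lo, hi = p["d_range_mm"]
            d = rng.uniform(lo, hi, n_per_species)
        h = a * d + b + rng.normal(0.0, sigma, n_per_species)
        h = np.where(h <= 0, a * d + b, h)
        out.extend(Measurement(species=sp, d=float(di), h=float(hi_)) for di, hi_ in zip(d, h))
    return out


def write_scene(
    out_dir,
    frame: Frame,
    detections: Sequence[Detection],
    masks: Sequence[BinaryMask],
    ground_truth: dict,
    ply_format: str = "binary_little_endian",
) -> dict[str, Path]:
    """Write a rendered scene in the formats scene_io reads.

    Produces ``frame.png``, ``frame.ply``, ``frame.txt`` (YOLO, species
    index = position in sorted label set), per-detection mask PNGs and
    ``ground_truth.json``; returns the path map.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fid = frame.frame_id
    paths = {
        "image": out / f"{fid}.png",
        "cloud": out / f"{fid}.ply",
        "detections": out / f"{fid}.txt",
        "ground_truth": out / "ground_truth.json",
        "class_map": out / "classes.txt",
    }
    iio.imwrite(paths["image"], frame.image)
    write_organized_ply(paths["cloud"], frame.cloud, fmt=ply_format)
    labels = sorted({d.label for d in detections})
    h, w = frame.shape
    lines = []
    for det in detections:
        x0, y0, x1, y1 = det.bbox
        lines.append(
            f"{labels.index(det.label)} {(x0 + x1) / 2 / w:.8f} {(y0 + y1) / 2 / h:.8f} "
            f"{(x1 - x0) / w:.8f} {(y1 - y0) / h:.8f} {det.confidence:.4f}"
        )
    paths["detections"].write_text("\n".join(lines) + ("\n" if lines else ""))
    paths["class_map"].write_text("\n".join(labels) + ("\n" if labels else ""))
    for k, mask in enumerate(masks):
        write_mask(out / f"{fid}_det{k}.png", mask)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(ground_truth, fh, indent=2)
        fh.write("\n")
    return paths
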