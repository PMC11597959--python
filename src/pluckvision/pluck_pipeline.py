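"""End-to-end orchestration: detections → cleaned masks → pose →
morphometry → h prediction → 3D plucking point.

The stages run in cascade per flower.  Any per-flower failure is
contained as a result status (``occluded_skipped``, ``no_depth``,
``degenerate``) rather than an exception, so one bad flower can never
abort a frame — only a missing calibration for a detected species is a
configuration error, raised before any processing starts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mask_ops, morphometry, pose3d
from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    DegenerateHullError,
    InsufficientDepthError,
    NoDepthError,
)
from .pluck_calibration import BoundaryLine, CalibrationModel, predict_h
from .scene_io import BinaryMask, Detection, FlowerResult, Frame

__all__ = ["PipelineConfig", "compute_pluck_point", "process_frame"]

log = logging.getLogger("pluckvision")


@dataclass
class PipelineConfig:
    """Knobs of the geometric pipeline.

    calibrations maps species label -> (CalibrationModel, BoundaryLine);
    ``default_species`` supplies a calibration for unmapped labels.
    ``use_boundary`` selects the upper-boundary line (the operating mode:
    cut below the calyx for ~coverage of flowers) over the bare
    regression line.
    """

    calibrations: dict[str, tuple[CalibrationModel, BoundaryLine]] = field(default_factory=dict)
    default_species: str | None = None
    use_boundary: bool = True
    main_axis_rule: str = "min_variance"
    diameter_method: str = "max_caliper"
    min_gap_px: int = 3
    min_points: int = 3
    top_fraction: float = 0.1


def compute_pluck_point(center_3d, main_axis, h_mm: float) -> np.ndarray:
    """Translate the flower center down the main axis by h.

    ``pluck = center + (h_mm / 1000) · main_axis`` (meters).
    """
    axis = np.asarray(main_axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("main_axis must be unit length")
    if h_mm < 0:
        raise ValueError("h must be non-negative")
    return np.asarray(center_3d, dtype=float) + (h_mm / 1000.0) * axis


def _line_for(det: Detection, config: PipelineConfig):
    species = det.label if det.label in config.calibrations else config.default_species
    model, boundary = config.calibrations[species]
    return boundary if config.use_boundary else model


def process_frame(
    frame: Frame,
    detections: Sequence[Detection],
    masks: Sequence[BinaryMask],
    config: PipelineConfig,
) -> list[FlowerResult]:
    """Run the full geometric cascade on one frame.

    Returns one :class:`FlowerResult` per detection, in order.  Masks are
    cleaned (nearest-component rule), occluded flowers are skipped, each
    remaining flower gets pose (PCA), diameter (convex polygon), center
    (Chebyshev + top points), predicted h and the 3D plucking point.
    """
    if len(detections) != len(masks):
        raise ValueError("need exactly one raw mask per detection")
    missing = sorted(
        {d.label for d in detections}
        - set(config.calibrations)
        - ({config.default_species} if config.default_species in config.calibrations else set())
    )
    if missing and config.default_species not in config.calibrations:
        raise ConfigurationError(
            f"no calibration for species {missing}; add them or set a default"
        )

    t0 = time.perf_counter()
    cleaned: list[BinaryMask | None] = []
    for det, mask in zip(detections, masks):
        try:
            cleaned.append(mask_ops.clean_mask(mask, det.bbox))
        except Exception:
            cleaned.append(None)
    present = [m for m in cleaned if m is not None]
    occ = mask_ops.flag_occlusions(present, frame.depth, min_gap_px=config.min_gap_px)
    occ_iter = iter(occ)
    status_map = [None if m is None else next(occ_iter) for m in cleaned]
    log.debug("mask cleaning + occlusion flags: %.3fs", time.perf_counter() - t0)

    results: list[FlowerResult] = []
    for det, mask, occ_status in zip(detections, cleaned, status_map):
        if mask is None:
            results.append(FlowerResult(detection=det, status="degenerate"))
            continue
        if occ_status == "occluded":
            results.append(FlowerResult(detection=det, status="occluded_skipped"))
            continue
        t1 = time.perf_counter()
        try:
            cloud = pose3d.isolate_points(frame, mask, min_points=config.min_points)
            pose = pose3d.pca_pose(cloud, main_axis_rule=config.main_axis_rule)
            diameter = morphometry.flower_diameter_mm(
                cloud, pose, method=config.diameter_method
            )
            center_px, center = morphometry.center_point_3d(
                cloud, mask, top_fraction=config.top_fraction
            )
            h_mm = float(predict_h(_line_for(det, config), diameter))
            pluck = compute_pluck_point(center, pose.main_axis, h_mm)
        except InsufficientDepthError:
            results.append(FlowerResult(detection=det, status="no_depth"))
            continue
        except NoDepthError:
            results.append(FlowerResult(detection=det, status="no_depth"))
            continue
        except (DegenerateGeometryError, DegenerateHullError):
            results.append(FlowerResult(detection=det, status="degenerate"))
            continue
        log.debug(
            "flower %r: pose+morphometry+pluck in %.3fs", det.label, time.perf_counter() - t1
        )
        results.append(
            FlowerResult(
                detection=det,
                status="ok",
                center_px=center_px,
                center_3d=tuple(center),
                diameter_mm=diameter,
                h_mm=h_mm,
                pluck_point_3d=tuple(pluck),
                axes=pose,
            )
        )
    return results
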