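"""Pluggable sources of detections and masks.

Deep detectors/segmenters are external to this package: their boxes and
masks arrive through files.  A classical HSV color-blob detector is
provided as a GPU-free fallback so the geometric pipeline can run
end-to-end on synthetic or simple real scenes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from skimage import color, measure

from .errors import MaskMissingError
from .scene_io import BinaryMask, Detection, Frame, load_mask

__all__ = ["color_blob_detect", "hsv_in_range", "attach_masks", "mask_filename"]


def hsv_in_range(
    image: np.ndarray,
    color_low: tuple[float, float, float],
    color_high: tuple[float, float, float],
) -> np.ndarray:
    """Boolean mask of pixels inside an HSV range.

    Hue is in degrees [0, 360) and may wrap (low > high means the range
    crosses 0°, handled as the union of two intervals); saturation and
    value are in [0, 1].
    """
    hsv = color.rgb2hsv(np.asarray(image, dtype=np.uint8))
    hue = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]
    h_lo, s_lo, v_lo = color_low
    h_hi, s_hi, v_hi = color_high
    if h_lo <= h_hi:
        hue_ok = (hue >= h_lo) & (hue <= h_hi)
    else:  # wrap across 0 degrees
        hue_ok = (hue >= h_lo) | (hue <= h_hi)
    return hue_ok & (sat >= s_lo) & (sat <= s_hi) & (val >= v_lo) & (val <= v_hi)


def color_blob_detect(
    image: np.ndarray,
    color_low: tuple[float, float, float],
    color_high: tuple[float, float, float],
    min_area_px: int = 50,
    label: str = "flower",
) -> list[Detection]:
    """Detect connected in-range color blobs as Detections.

    One detection per 8-connected component with ``area >= min_area_px``;
    confidence is the component's fill ratio (area / bbox area).  Purely
    classical: a stand-in input source, not a learned detector.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    in_range = hsv_in_range(image, color_low, color_high)
    labeled = measure.label(in_range, connectivity=2)
    dets: list[Detection] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open rows/cols
        conf = float(region.area) / float((r1 - r0) * (c1 - c0))
        dets.append(
            Detection(
                bbox=(float(c0), float(r0), float(c1), float(r1)),
                label=label,
                confidence=min(1.0, conf),
            )
        )
    # deterministic order: top-left to bottom-right
    dets.sort(key=lambda d: (d.bbox[1], d.bbox[0]))
    return dets


def mask_filename(frame_id: str, det_index: int) -> str:
    """Canonical external mask filename for detection ``det_index``."""
    return f"{frame_id}_det{det_index}.png"


def attach_masks(
    frame: Frame,
    detections: Sequence[Detection],
    mask_source: str = "files",
    mask_dir=None,
    color_low: tuple[float, float, float] | None = None,
    color_high: tuple[float, float, float] | None = None,
) -> list[tuple[Detection, BinaryMask]]:
    """Pair each detection with a raw (uncleaned) binary mask.

    ``mask_source="files"`` loads one externally produced mask per
    detection from ``mask_dir`` (named ``<frame_id>_det<k>.png``);
    ``"fallback_threshold"`` synthesizes a mask by HSV thresholding inside
    the bbox.  In both modes the returned mask is zeroed outside its
    detection's bounding box.
    """
    pairs: list[tuple[Detection, BinaryMask]] = []
    h, w = frame.shape
    for k, det in enumerate(detections):
        if mask_source == "files":
            if mask_dir is None:
                raise ValueError("mask_dir is required with mask_source='files'")
            path = Path(mask_dir) / mask_filename(frame.frame_id, k)
            if not path.exists():
                raise MaskMissingError(k, path)
            mask = load_mask(path)
            if mask.shape != frame.shape:
                raise ValueError(
                    f"mask {path} shape {mask.shape} != frame shape {frame.shape}"
                )
            grid = mask.grid
            provenance = "external"
        elif mask_source == "fallback_threshold":
            if color_low is None or color_high is None:
                raise ValueError("fallback_threshold needs color_low/color_high")
            grid = hsv_in_range(frame.image, color_low, color_high)
            provenance = "fallback"
        else:
            raise ValueError(f"unknown mask_source {mask_source!r}")
        keep = np.zeros((h, w), dtype=bool)
        x0, y0, x1, y1 = det.bbox
        r0, c0 = max(0, int(np.floor(y0))), max(0, int(np.floor(x0)))
        r1, c1 = min(h, int(np.ceil(y1))), min(w, int(np.ceil(x1)))
        keep[r0:r1, c0:c1] = True
        pairs.append((det, BinaryMask(grid=grid & keep, provenance=provenance)))
    return pairs
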