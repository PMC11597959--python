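"""Mask cleaning and occlusion flagging.

Zero-shot segmentation masks prompted by a bounding box frequently come
back as several separated polygons, only one of which is the flower the
box was drawn around.  The cleaning rule keeps the connected component
whose centroid lies closest to the bounding-box center.  When two cleaned
masks (nearly) touch, the deeper flower is flagged as occluded and skipped
— it will be fully exposed on a later harvesting pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import NoComponentError
from .scene_io import BinaryMask

__all__ = ["Component", "split_components", "select_component", "clean_mask", "flag_occlusions"]


@dataclass
class Component:
    """One 8-connected blob of a mask: its pixels, area and centroid (u, v)."""

    pixels: np.ndarray  # (N, 2) array of (row, col)
    area_px: int
    centroid_px: tuple[float, float]  # (u, v) = (col, row)


def split_components(mask: BinaryMask) -> list[Component]:
    """Split a mask into 8-connected components, largest first.

    Each component's centroid is the mean of its member pixel coordinates,
    reported as (u, v).  An all-false mask yields an empty list.
    """
    labeled = measure.label(mask.grid, connectivity=2)
    comps: list[Component] = []
    for region in measure.regionprops(labeled):
        r_mean, c_mean = region.centroid
        comps.append(
            Component(
                pixels=region.coords,
                area_px=int(region.area),
                centroid_px=(float(c_mean), float(r_mean)),
            )
        )
    comps.sort(key=lambda c: -c.area_px)
    return comps


def select_component(
    components: Sequence[Component], bbox: tuple[float, float, float, float]
) -> Component:
    """Pick the component whose centroid is closest to the bbox center.

    Ties go to the larger area, then to the lower index in ``components``.
    """
    if not components:
        raise NoComponentError("no component to select")
    x0, y0, x1, y1 = bbox
    bu, bv = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    best = min(
        range(len(components)),
        key=lambda i: (
            np.hypot(components[i].centroid_px[0] - bu, components[i].centroid_px[1] - bv),
            -components[i].area_px,
            i,
        ),
    )
    return components[best]


def clean_mask(mask: BinaryMask, bbox: tuple[float, float, float, float]) -> BinaryMask:
    """Reduce a mask to the single component nearest the bbox center."""
    comp = select_component(split_components(mask), bbox)
    grid = np.zeros(mask.shape, dtype=bool)
    grid[comp.pixels[:, 0], comp.pixels[:, 1]] = True
    return BinaryMask(grid=grid, provenance=mask.provenance)


def flag_occlusions(
    masks: Sequence[BinaryMask],
    depth: np.ndarray,
    min_gap_px: int = 3,
) -> list[str]:
    """Classify each mask as ``"complete"`` or ``"occluded"``.

    A mask is occluded iff its dilation by ``min_gap_px`` intersects
    another mask *and* its mean depth is greater (it lies beneath); of an
    overlapping pair exactly the deeper one is flagged.  ``depth`` is the
    frame's H x W z-grid in meters (NaN = invalid).
    """
    depth = np.asarray(depth, dtype=float)
    n = len(masks)
    if n == 0:
        return []
    dilated = []
    means = []
    for m in masks:
        if m.shape != depth.shape:
            raise ValueError("masks and depth grid must share dimensions")
        dilated.append(
            ndimage.binary_dilation(m.grid, iterations=min_gap_px) if min_gap_px > 0 else m.grid
        )
        z = depth[m.grid]
        z = z[np.isfinite(z)]
        means.append(float(np.mean(z)) if z.size else np.inf)
    status = ["complete"] * n
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(dilated[i] & masks[j].grid) or np.any(dilated[j] & masks[i].grid):
                # deeper of the pair lies beneath; ties keep both complete
                if means[i] > means[j]:
                    status[i] = "occluded"
                elif means[j] > means[i]:
                    status[j] = "occluded"
    return status
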