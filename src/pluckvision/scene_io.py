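"""Data model and I/O for frames, detections, masks, measurements, results.

Conventions used throughout the package:

* pixels are 0-based, origin top-left, ``u`` = column, ``v`` = row;
  bounding boxes are half-open ``(x_min, y_min, x_max, y_max)``;
* the camera frame is +X right, +Y down, +Z forward (into the canopy for a
  downward-looking bench camera); cloud coordinates are in meters;
* morphometry and calibration work in millimeters — the single m→mm
  conversion lives in the pipeline / morphometry layer, never here.

An *organized* point cloud is stored on the image's pixel grid: one 3D
point per pixel, with an all-NaN triple marking invalid depth.  The disk
format is PLY (ascii or binary little-endian) with ``obj_info width`` /
``obj_info height`` lines carrying the grid shape.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, GridMismatchError

__all__ = [
    "Frame",
    "Detection",
    "BinaryMask",
    "Measurement",
    "FlowerResult",
    "load_frame",
    "load_detections",
    "load_mask",
    "write_mask",
    "read_organized_ply",
    "write_organized_ply",
    "write_results",
    "read_results",
    "write_results_csv",
    "load_measurements",
    "write_measurements",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    """An RGB image plus the organized point cloud sharing its pixel grid.

    Attributes
    ----------
    image : (H, W, 3) uint8 array
    cloud : (H, W, 3) float array, meters, camera frame; an invalid pixel
        is an all-NaN triple.
    frame_id : str
    """

    image: np.ndarray
    cloud: np.ndarray
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.cloud = np.asarray(self.cloud, dtype=float)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if self.cloud.shape != self.image.shape:
            raise GridMismatchError(
                f"grid mismatch: image {self.image.shape[:2]} vs "
                f"cloud {self.cloud.shape[:2] if self.cloud.ndim == 3 else self.cloud.shape}"
            )
        finite = np.isfinite(self.cloud)
        mixed = finite.any(axis=2) & ~finite.all(axis=2)
        if mixed.any():
            raise ValueError("cloud points must be all-finite or all-NaN")
        z = self.cloud[..., 2]
        if np.any(z[np.isfinite(z)] <= 0):
            raise ValueError("finite cloud points must have z > 0 (in front of camera)")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the shared pixel grid."""
        return self.image.shape[:2]

    @property
    def depth(self) -> np.ndarray:
        """H x W z-grid in meters (NaN where depth is invalid)."""
        return self.cloud[..., 2]

    def finite_count(self) -> int:
        return int(np.isfinite(self.cloud[..., 2]).sum())


@dataclass(frozen=True)
class Detection:
    """One detected flower: half-open pixel box, species label, confidence."""

    bbox: tuple[float, float, float, float]
    label: str
    confidence: float = 1.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"empty bbox {self.bbox}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def clipped(self, width: int, height: int) -> "Detection":
        x0, y0, x1, y1 = self.bbox
        return dataclasses.replace(
            self,
            bbox=(max(0.0, x0), max(0.0, y0), min(float(width), x1), min(float(height), y1)),
        )


@dataclass
class BinaryMask:
    """A boolean H x W mask tied to one frame (and usually one detection)."""

    grid: np.ndarray
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def area(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class Measurement:
    """One calibrated flower: species, diameter d (mm), total height h (mm).

    ``h`` is the distance from the top of the flower down to the plucking
    point just below the calyx.
    """

    species: str
    d: float
    h: float

    def __post_init__(self) -> None:
        if not (self.d > 0 and self.h > 0):
            raise ValueError("d and h must be positive (mm)")


#: allowed FlowerResult statuses
RESULT_STATUSES = ("ok", "occluded_skipped", "no_depth", "degenerate")


@dataclass
class FlowerResult:
    """Full per-flower output of the pipeline.

    When ``status != "ok"`` the geometric fields are ``None`` and serialize
    to JSON null.
    """

    detection: Detection
    status: str
    center_px: tuple[float, float] | None = None
    center_3d: tuple[float, float, float] | None = None
    diameter_mm: float | None = None
    h_mm: float | None = None
    pluck_point_3d: tuple[float, float, float] | None = None
    axes: "object | None" = None  # pose3d.PoseEstimate; kept loose to avoid a cycle

    def __post_init__(self) -> None:
        if self.status not in RESULT_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "ok":
            for name in ("center_px", "center_3d", "diameter_mm", "h_mm", "pluck_point_3d"):
                val = getattr(self, name)
                if val is None or not np.all(np.isfinite(val)):
                    raise ValueError(f"status=ok requires finite {name}")


# ---------------------------------------------------------------------------
# organized PLY
# ---------------------------------------------------------------------------

def write_organized_ply(path, cloud: np.ndarray, fmt: str = "binary_little_endian") -> None:
    """Write an H x W x 3 organized cloud as PLY with grid metadata.

    NaN points are written as NaN vertices (never dropped) so the grid
    stays pixel-aligned.
    """
    cloud = np.asarray(cloud, dtype=np.float32)
    if cloud.ndim != 3 or cloud.shape[2] != 3:
        raise ValueError("cloud must be H x W x 3")
    h, w = cloud.shape[:2]
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported PLY format {fmt!r}")
    header = [
        "ply",
        f"format {fmt} 1.0",
        f"obj_info width {w}",
        f"obj_info height {h}",
        f"element vertex {h * w}",
        "property float x",
        "property float y",
        "property float z",
        "end_header",
    ]
    flat = cloud.reshape(-1, 3)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if fmt == "ascii":
            lines = "\n".join(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in flat)
            fh.write(lines.encode("ascii") + b"\n")
        else:
            fh.write(np.ascontiguousarray(flat, dtype="<f4").tobytes())


def read_organized_ply(path) -> np.ndarray:
    """Read an organized PLY written by :func:`write_organized_ply`.

    Returns an H x W x 3 float array.  Raises :class:`FormatError` when the
    file lacks grid metadata or x/y/z float vertices.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise FormatError(f"{path}: not a PLY file")
    end_line = data.index(b"\n", end)
    header = data[:end_line].decode("ascii", "replace").splitlines()
    body = data[end_line + 1:]

    fmt = None
    width = height = None
    n_vertex = None
    props: list[str] = []
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "obj_info" and len(tok) >= 3 and tok[1] in ("width", "height"):
            if tok[1] == "width":
                width = int(tok[2])
            else:
                height = int(tok[2])
        elif tok[0] == "comment" and len(tok) >= 3 and tok[1] in ("width", "height"):
            # tolerate clouds that stash the grid in comments
            if tok[1] == "width":
                width = int(tok[2])
            else:
                height = int(tok[2])
        elif tok[0] == "element" and tok[1] == "vertex":
            n_vertex = int(tok[2])
        elif tok[0] == "property" and n_vertex is not None:
            props.append(tok[2])
    if fmt not in ("ascii", "binary_little_endian"):
        raise FormatError(f"{path}: unsupported PLY format {fmt!r}")
    if width is None or height is None:
        raise FormatError(f"{path}: PLY lacks obj_info width/height grid metadata")
    if n_vertex != width * height:
        raise FormatError(
            f"{path}: vertex count {n_vertex} != width*height {width * height}"
        )
    if props[:3] != ["x", "y", "z"]:
        raise FormatError(f"{path}: expected x,y,z as leading vertex properties")

    n_props = len(props)
    if fmt == "ascii":
        vals = np.array(body.split(), dtype=float)
        if vals.size < n_vertex * n_props:
            raise FormatError(f"{path}: truncated ascii vertex data")
        arr = vals[: n_vertex * n_props].reshape(n_vertex, n_props)[:, :3]
    else:
        need = n_vertex * n_props * 4
        if len(body) < need:
            raise FormatError(f"{path}: truncated binary vertex data")
        arr = np.frombuffer(body[:need], dtype="<f4").reshape(n_vertex, n_props)[:, :3]
    return arr.astype(float).reshape(height, width, 3)


# ---------------------------------------------------------------------------
# frame / detections / masks
# ---------------------------------------------------------------------------

def load_frame(image_path, cloud_path, frame_id: str | None = None) -> Frame:
    """Load an RGB image and its organized PLY cloud into a :class:`Frame`.

    The PLY grid metadata must match the image dimensions; NaN points are
    preserved, never interpolated or dropped.
    """
    image = np.asarray(iio.imread(image_path))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[2] == 4:
        image = image[..., :3]
    cloud = read_organized_ply(cloud_path)
    if cloud.shape[:2] != image.shape[:2]:
        raise GridMismatchError(
            f"grid mismatch: image {image.shape[:2]} vs cloud {cloud.shape[:2]}"
        )
    if frame_id is None:
        frame_id = Path(image_path).stem
    return Frame(image=image, cloud=cloud, frame_id=frame_id)


def load_mask(path) -> BinaryMask:
    """Read a single-channel 8-bit PNG mask (0 background, >0 flower)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(grid=arr > 0, provenance="external")


def write_mask(path, mask: BinaryMask) -> None:
    iio.imwrite(path, (mask.grid.astype(np.uint8) * 255))


def load_detections(
    path,
    dialect: str,
    image_size: tuple[int, int],
    class_map: Sequence[str] | None = None,
    default_label: str = "flower",
) -> list[Detection]:
    """Parse detections from YOLO txt or COCO JSON into pixel-corner boxes.

    Parameters
    ----------
    dialect : {"yolo_txt", "coco_json"}
    image_size : (W, H) of the frame the boxes refer to.
    class_map : optional sequence mapping class index -> species label.
        Without it, only class index 0 is accepted (mapped to
        ``default_label``).

    YOLO lines are ``class cx cy w h [confidence]`` with all geometry
    normalized to [0, 1]; COCO boxes are absolute ``[x, y, w, h]``.  Output
    boxes are absolute half-open pixel corners, clipped to image bounds,
    in file order.
    """
    width, height = image_size
    dets: list[Detection] = []
    if dialect == "yolo_txt":
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise FormatError(f"{path}:{lineno}: expected 5 or 6 fields")
            try:
                cls = int(parts[0])
                cx, cy, w, h = map(float, parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            for name, val in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
                if not (0.0 <= val <= 1.0):
                    raise FormatError(
                        f"{path}:{lineno}: normalized {name}={val} outside [0, 1]"
                    )
            label = _resolve_label(cls, class_map, default_label, f"{path}:{lineno}")
            bbox = (
                (cx - w / 2) * width,
                (cy - h / 2) * height,
                (cx + w / 2) * width,
                (cy + h / 2) * height,
            )
            dets.append(Detection(bbox=bbox, label=label, confidence=conf).clipped(width, height))
    elif dialect == "coco_json":
        with open(path) as fh:
            doc = json.load(fh)
        if isinstance(doc, dict):
            anns = doc.get("annotations", [])
            cats = {c["id"]: c["name"] for c in doc.get("categories", [])}
        else:
            anns, cats = doc, {}
        for i, ann in enumerate(anns):
            try:
                x, y, w, h = ann["bbox"]
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}: annotation {i}: bad bbox") from exc
            if w <= 0 or h <= 0:
                raise FormatError(f"{path}: annotation {i}: non-positive box size")
            cid = ann.get("category_id", 0)
            if cats:
                if cid not in cats:
                    raise FormatError(f"{path}: annotation {i}: unknown category_id {cid}")
                label = cats[cid]
            else:
                label = _resolve_label(cid, class_map, default_label, f"{path}: annotation {i}")
            conf = float(ann.get("score", 1.0))
            dets.append(
                Detection(bbox=(x, y, x + w, y + h), label=label, confidence=conf).clipped(
                    width, height
                )
            )
    else:
        raise ValueError(f"unknown detection dialect {dialect!r}")
    return dets


def _resolve_label(cls: int, class_map, default_label: str, where: str) -> str:
    if class_map is not None:
        if not (0 <= cls < len(class_map)):
            raise FormatError(f"{where}: class index {cls} outside class map")
        return class_map[cls]
    if cls != 0:
        raise FormatError(f"{where}: class index {cls} without a class map")
    return default_label


# ---------------------------------------------------------------------------
# results JSON / CSV
# ---------------------------------------------------------------------------

def _result_to_record(r: FlowerResult) -> dict:
    axes = None
    if r.axes is not None:
        axes = {
            "e1": list(map(float, r.axes.e1)),
            "e2": list(map(float, r.axes.e2)),
            "e3": list(map(float, r.axes.e3)),
            "eigenvalues": list(map(float, r.axes.eigenvalues)),
            "main_axis": list(map(float, r.axes.main_axis)),
            "centroid": list(map(float, r.axes.centroid)),
        }
    return {
        "detection": {
            "bbox": list(map(float, r.detection.bbox)),
            "label": r.detection.label,
            "confidence": float(r.detection.confidence),
        },
        "status": r.status,
        "center_px": None if r.center_px is None else list(map(float, r.center_px)),
        "center_3d": None if r.center_3d is None else list(map(float, r.center_3d)),
        "diameter_mm": None if r.diameter_mm is None else float(r.diameter_mm),
        "h_mm": None if r.h_mm is None else float(r.h_mm),
        "pluck_point_3d": None
        if r.pluck_point_3d is None
        else list(map(float, r.pluck_point_3d)),
        "axes": axes,
    }


def write_results(results: Sequence[FlowerResult], path) -> None:
    """Write results as a JSON document (one record per flower)."""
    doc = {"results": [_result_to_record(r) for r in results]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> list[FlowerResult]:
    """Read back a results JSON written by :func:`write_results`."""
    from .pose3d import PoseEstimate  # local import: avoid module cycle

    with open(path) as fh:
        doc = json.load(fh)
    out: list[FlowerResult] = []
    for rec in doc["results"]:
        det = Detection(
            bbox=tuple(rec["detection"]["bbox"]),
            label=rec["detection"]["label"],
            confidence=rec["detection"]["confidence"],
        )
        axes = None
        if rec["axes"] is not None:
            a = rec["axes"]
            axes = PoseEstimate(
                e1=np.array(a["e1"]),
                e2=np.array(a["e2"]),
                e3=np.array(a["e3"]),
                eigenvalues=tuple(a["eigenvalues"]),
                main_axis=np.array(a["main_axis"]),
                centroid=np.array(a["centroid"]),
            )
        out.append(
            FlowerResult(
                detection=det,
                status=rec["status"],
                center_px=None if rec["center_px"] is None else tuple(rec["center_px"]),
                center_3d=None if rec["center_3d"] is None else tuple(rec["center_3d"]),
                diameter_mm=rec["diameter_mm"],
                h_mm=rec["h_mm"],
                pluck_point_3d=None
                if rec["pluck_point_3d"] is None
                else tuple(rec["pluck_point_3d"]),
                axes=axes,
            )
        )
    return out


def write_results_csv(results: Sequence[FlowerResult], path) -> None:
    """Flat CSV export (one row per flower; vectors as separate columns)."""
    cols = [
        "label", "confidence", "status",
        "bbox_x0", "bbox_y0", "bbox_x1", "bbox_y1",
        "center_u", "center_v",
        "center_x_m", "center_y_m", "center_z_m",
        "diameter_mm", "h_mm",
        "pluck_x_m", "pluck_y_m", "pluck_z_m",
    ]
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(cols)
        for r in results:
            cpx = r.center_px or (None, None)
            c3d = r.center_3d or (None, None, None)
            p3d = r.pluck_point_3d or (None, None, None)
            wr.writerow(
                [r.detection.label, r.detection.confidence, r.status,
                 *r.detection.bbox, *cpx, *c3d, r.diameter_mm, r.h_mm, *p3d]
            )


# ---------------------------------------------------------------------------
# measurements CSV
# ---------------------------------------------------------------------------

def load_measurements(path) -> list[Measurement]:
    """Read a measurements CSV with header ``species,d_mm,h_mm``."""
    out: list[Measurement] = []
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh)
        required = {"species", "d_mm", "h_mm"}
        if rd.fieldnames is None or not required.issubset(rd.fieldnames):
            raise FormatError(f"{path}: measurements CSV needs header species,d_mm,h_mm")
        for row in rd:
            out.append(
                Measurement(species=row["species"], d=float(row["d_mm"]), h=float(row["h_mm"]))
            )
    return out


def write_measurements(measurements: Iterable[Measurement], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["species", "d_mm", "h_mm"])
        for m in measurements:
            wr.writerow([m.species, repr(m.d), repr(m.h)])
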