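"""Exception hierarchy for the pluckvision pipeline.

Per-flower failures (insufficient depth, degenerate geometry, missing
component) are caught by the pipeline and turned into per-record statuses;
configuration and I/O problems abort a run.
"""


class PluckVisionError(Exception):
    """Base class for all pluckvision errors."""


class GridMismatchError(PluckVisionError):
    """Image and organized point cloud do not share one pixel grid."""


class FormatError(PluckVisionError):
    """A detection / mask / measurement file violates its dialect."""


class MaskMissingError(PluckVisionError):
    """An expected external mask file is absent."""

    def __init__(self, detection_index: int, path=None):
        self.detection_index = detection_index
        self.path = path
        msg = f"mask missing for detection index {detection_index}"
        if path is not None:
            msg += f" (expected {path})"
        super().__init__(msg)


class NoComponentError(PluckVisionError):
    """A mask contains no connected component to select."""


class InsufficientDepthError(PluckVisionError):
    """Fewer than the minimum number of finite 3D points under a mask."""

    def __init__(self, n_finite: int, n_required: int = 3):
        self.n_finite = n_finite
        self.n_required = n_required
        super().__init__(
            f"insufficient depth: {n_finite} finite points (need >= {n_required})"
        )


class DegenerateGeometryError(PluckVisionError):
    """Point set is rank-deficient (e.g. collinear): pose is undefined."""


class DegenerateHullError(PluckVisionError):
    """Fewer than 3 non-collinear points: convex hull is undefined."""


class NoDepthError(PluckVisionError):
    """No finite depth available near the flower center pixel."""


class InsufficientDataError(PluckVisionError):
    """Too few measurements to fit a calibration model."""


class NoCalibrationError(PluckVisionError):
    """No calibration available for the requested species."""

    def __init__(self, species: str, known):
        self.species = species
        self.known = sorted(known)
        super().__init__(
            f"no calibration for species {species!r}; known species: {self.known}"
        )


class ConfigurationError(PluckVisionError):
    """A run is mis-configured (detected before any frame is processed)."""
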