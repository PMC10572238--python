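"""The full measurement pipeline and its configuration.

Stage order (the selected processing chain: 7 x 7 Gaussian template, 3 x 3
Sobel template, disc-3 closing, Otsu binarisation, 20-px inward shift):

1. channel extraction     -> intensity grid in [0, 1]
2. Gaussian denoising     -> speckle-smoothed grid
3. Sobel edge detection   -> edge mask (border-replicated response)
4. morphological closing  -> joined edge map, filled to the spot support
5. binarisation           -> foreground mask of the denoised intensity;
                             the connected component overlapping the edge
                             support is kept and hole-filled
6. inward shift           -> boundary eroded inward by the configured offset
7. ellipse fit            -> degree of orientation (a/b)^2

The binarisation cuts the boundary on an iso-intensity contour of the
denoised spot rather than on the rim of the gradient ring: iso-intensity
contours of an elliptical-decay spot all share one axis ratio, which makes
the statistic insensitive to the exact threshold, while the closed edge map
localises which component is the spot.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from typing import Any

import numpy as np
from scipy import ndimage

from .exceptions import PipelineStageError, ValidationError
from .image import ChannelMode, extract_intensity
from . import preprocess as pp
from .ellipse import (
    BoundaryPath,
    FittedEllipse,
    degree_of_orientation,
    fit_ellipse_lsq,
    fit_rms_distance,
    shift_boundary_inward,
)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the measurement chain, with the selected defaults."""

    channel: str = "red"
    gaussian_size: int = 7
    gaussian_sigma: float | None = None  # None -> width tied to template size
    sobel_template: int = 3
    edge_threshold_factor: float = 4.0
    morphology_shape: str = "disc"
    morphology_radius: int = 3
    binarise_method: str = "otsu"
    binarise_threshold: float | None = None
    inward_offset: int = 20

    def digest(self) -> str:
        """Stable short hash of the configuration, for result provenance."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        """Read nested keys (``gaussian.size``, ``edge.sobel_template``,
        ``morphology.shape``, ``binarise.method`` ...) from a TOML file."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict[str, Any] = {}
        mapping = {
            ("channel",): "channel",
            ("gaussian", "size"): "gaussian_size",
            ("gaussian", "sigma"): "gaussian_sigma",
            ("edge", "sobel_template"): "sobel_template",
            ("edge", "threshold_factor"): "edge_threshold_factor",
            ("morphology", "shape"): "morphology_shape",
            ("morphology", "radius"): "morphology_radius",
            ("binarise", "method"): "binarise_method",
            ("binarise", "threshold"): "binarise_threshold",
            ("inward_offset",): "inward_offset",
        }
        for keys, attr in mapping.items():
            node = raw
            for k in keys:
                if not isinstance(node, dict) or k not in node:
                    node = None
                    break
                node = node[k]
            if node is not None:
                flat[attr] = node
        return cls(**flat)


@dataclass(frozen=True)
class StageOutputs:
    """Intermediate images, retained when debugging is requested."""

    intensity: np.ndarray
    denoised: np.ndarray
    edges: np.ndarray
    closed: np.ndarray
    binary: np.ndarray


@dataclass(frozen=True)
class OrientationResult:
    """Fitted ellipse, the orientation statistic, and run provenance."""

    ellipse: FittedEllipse
    degree_of_orientation: float
    config_digest: str
    boundary_point_count: int
    fit_rms: float
    boundary: BoundaryPath | None = field(default=None, repr=False)
    stages: StageOutputs | None = field(default=None, repr=False)

    def to_record(self, file: str = "") -> dict[str, Any]:
        """Flat record for CSV/JSON output."""
        el = self.ellipse
        return {
            "file": file,
            "centre_row": round(el.centre[0], 3),
            "centre_col": round(el.centre[1], 3),
            "a": round(el.a, 3),
            "b": round(el.b, 3),
            "tilt_deg": round(np.degrees(el.tilt), 3),
            "degree_of_orientation": round(self.degree_of_orientation, 6),
            "boundary_points": self.boundary_point_count,
            "fit_rms": round(self.fit_rms, 4),
            "config_digest": self.config_digest,
        }


def _select_spot_component(binary: np.ndarray, support: np.ndarray | None) -> np.ndarray:
    """Connected component of the binarised mask that best overlaps the
    closed-edge spot support (largest component if there is no support)."""
    labels, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        raise ValidationError("binarised image has no foreground")
    if support is None or not support.any():
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        return labels == sizes.argmax()
    overlap = ndimage.sum_labels(support.astype(np.float64), labels, index=np.arange(1, n + 1))
    if overlap.max() == 0:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        return labels == sizes.argmax()
    return labels == (1 + int(np.argmax(overlap)))


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    keep_stages: bool = False,
) -> OrientationResult:
    """Run the full measurement chain on one photograph.

    Raises :class:`PipelineStageError` naming the failing stage when any
    stage's preconditions are violated (e.g. a featureless image reaching
    binarisation).
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError as exc:
            raise PipelineStageError(name, str(exc)) from exc

    intensity = stage("extract_intensity", extract_intensity, image, config.channel)

    template = stage(
        "gaussian_denoise", pp.make_gaussian_template, config.gaussian_size, config.gaussian_sigma
    )
    denoised = stage("gaussian_denoise", pp.gaussian_denoise, intensity, template)

    edge_cfg = pp.EdgeConfig(
        sobel_template=config.sobel_template,
        threshold_factor=config.edge_threshold_factor,
    )
    edges = stage("sobel_edges", pp.sobel_edges, denoised, edge_cfg)

    se = pp.StructuringElement(shape=config.morphology_shape, radius=config.morphology_radius)
    closed = stage("morphological_close", pp.morphological_close, edges, se)

    support = None
    if closed.any():
        labels, n = ndimage.label(closed, structure=_EIGHT)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        support = ndimage.binary_fill_holes(labels == sizes.argmax())

    binary = stage(
        "binarise", pp.binarise, denoised, config.binarise_method, config.binarise_threshold
    )
    binary = stage("binarise", pp.morphological_close, binary, se)
    spot = stage("binarise", _select_spot_component, binary, support)

    path = stage("shift_boundary_inward", shift_boundary_inward, spot, config.inward_offset)
    el = stage("fit_ellipse_lsq", fit_ellipse_lsq, path)

    result = OrientationResult(
        ellipse=el,
        degree_of_orientation=degree_of_orientation(el),
        config_digest=config.digest(),
        boundary_point_count=len(path),
        fit_rms=fit_rms_distance(el, path),
        boundary=path,
        stages=StageOutputs(intensity, denoised, edges, closed, spot) if keep_stages else None,
    )
    return result
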