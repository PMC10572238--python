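"""Raster I/O and conversion of laser-spot photographs to intensity grids.

The imaging system photographs a red He-Ne laser spot (632.8 nm) transmitted
through a fibrous sample, so virtually all of the spot's signal lives in the
red channel; ``ChannelMode.RED`` is therefore the default conversion.  A
luminance mode (ITU-R BT.601 weights) and a per-pixel channel maximum are
kept for robustness studies with other light sources.

Conventions used throughout the package: images are ``H x W x 3`` uint8
arrays; intensity grids are ``H x W`` float arrays in [0, 1]; coordinates are
0-based ``(row, col)`` with the origin at the top-left corner.
"""

from __future__ import annotations

import enum
import os

import numpy as np
import imageio.v3 as iio

from .exceptions import ImageReadError, ValidationError

MIN_SIDE = 16

#: ITU-R BT.601 luma weights for (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class ChannelMode(str, enum.Enum):
    """How an RGB photograph is collapsed to a scalar intensity grid."""

    RED = "red"
    LUMINANCE = "luminance"
    MAX = "max"


def _as_uint8(pixels: np.ndarray) -> np.ndarray:
    if pixels.dtype == np.uint8:
        return pixels
    if pixels.dtype == np.uint16:
        # 16-bit cameras: map [0, 65535] onto [0, 255]; 257 = 65535 // 255.
        return (pixels // 257).astype(np.uint8)
    if np.issubdtype(pixels.dtype, np.floating):
        return np.clip(np.round(pixels * 255), 0, 255).astype(np.uint8)
    raise ImageReadError(f"unsupported sample dtype {pixels.dtype}")


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check the ``H x W x 3`` uint8 contract and return the array."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValidationError(f"expected uint8 samples, got {image.dtype}")
    h, w = image.shape[:2]
    if h < MIN_SIDE or w < MIN_SIDE:
        raise ValidationError(f"image too small ({h} x {w}); need at least {MIN_SIDE} px per side")
    return image


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Decode a PNG/TIFF/JPEG photograph into an ``H x W x 3`` uint8 array.

    Grayscale inputs are replicated across the three channels; 16-bit
    inputs are rescaled to 8 bits; an alpha channel, if present, is dropped.

    Raises
    ------
    ImageReadError
        If the file is missing, truncated, or not a decodable raster.
    ValidationError
        If the decoded image is smaller than 16 px on a side.
    """
    if not os.path.exists(path):
        raise ImageReadError(f"cannot read image file '{os.fspath(path)}': no such file")
    try:
        # decode through Pillow only: plugin fall-through gives unpredictable
        # error types and formats beyond PNG/TIFF/JPEG are not supported
        pixels = iio.imread(path, plugin="pillow")
    except Exception as exc:
        raise ImageReadError(f"cannot read image file '{os.fspath(path)}': {exc}") from exc
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    elif pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ImageReadError(
            f"'{os.fspath(path)}': unsupported image layout with shape {pixels.shape}"
        )
    if pixels.shape[0] == 0 or pixels.shape[1] == 0:
        raise ValidationError(f"'{os.fspath(path)}': zero-area image")
    return validate_image(_as_uint8(pixels))


def extract_intensity(image: np.ndarray, mode: ChannelMode | str = ChannelMode.RED) -> np.ndarray:
    """Collapse an RGB image to an ``H x W`` float intensity grid in [0, 1]."""
    image = validate_image(image)
    try:
        mode = ChannelMode(mode)
    except ValueError:
        raise ValidationError(
            f"unknown channel mode {mode!r}; expected one of "
            f"{[m.value for m in ChannelMode]}"
        ) from None
    rgb = image.astype(np.float64)
    if mode is ChannelMode.RED:
        grid = rgb[:, :, 0]
    elif mode is ChannelMode.LUMINANCE:
        wr, wg, wb = LUMA_WEIGHTS
        grid = wr * rgb[:, :, 0] + wg * rgb[:, :, 1] + wb * rgb[:, :, 2]
    else:
        grid = rgb.max(axis=2)
    return grid / 255.0


def validate_grid(grid: np.ndarray) -> np.ndarray:
    """Check the intensity-grid contract (2-D, finite, within [0, 1])."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.size == 0:
        raise ValidationError(f"expected non-empty 2-D grid, got shape {grid.shape}")
    if not np.isfinite(grid).all():
        raise ValidationError("intensity grid contains non-finite values")
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValidationError("intensity grid values must lie in [0, 1]")
    return grid
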