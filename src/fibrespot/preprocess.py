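"""Denoising and enhancement stages that turn a speckled spot into a mask.

Laser speckle — the granular interference pattern coherent light produces on
rough media — is the dominant noise on transmitted-spot photographs.  Four
stages clean it up before any geometry is measured:

1. Gaussian low-pass filtering with a small square template (default 7 x 7).
2. Sobel gradient-magnitude edge detection, with the image border replicated
   outward so edge responses at the frame boundary are not attenuated.
3. Morphological closing (dilation then erosion) with a small disc, joining
   discontinuous boundary pixels.
4. Binarisation, by Otsu's between-class-variance criterion over 256
   histogram bins or by a fixed threshold.

All operations take and return plain numpy arrays (float intensity grids in
[0, 1], boolean masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .image import validate_grid

# ---------------------------------------------------------------------------
# Gaussian denoising
# ---------------------------------------------------------------------------


def auto_sigma(size: int) -> float:
    """Kernel width tied to template size: 0.3 * ((size-1)/2 - 1) + 0.8."""
    return 0.3 * ((size - 1) / 2 - 1) + 0.8


@dataclass(frozen=True)
class GaussianTemplate:
    """Normalised square Gaussian weight matrix.

    ``weights[i, j] ∝ exp(-((i-c)^2 + (j-c)^2) / (2 sigma^2))`` with
    ``c = (size-1)/2``, normalised to unit sum.
    """

    size: int
    sigma: float
    weights: np.ndarray = field(repr=False)


def make_gaussian_template(size: int, sigma: float | None = None) -> GaussianTemplate:
    """Build a ``size x size`` Gaussian template; ``sigma=None`` uses the
    size-tied default width."""
    if not isinstance(size, (int, np.integer)) or size < 3 or size % 2 == 0:
        raise ValidationError(f"template size must be an odd integer >= 3, got {size!r}")
    if sigma is None:
        sigma = auto_sigma(size)
    if not sigma > 0:
        raise ValidationError(f"sigma must be positive, got {sigma!r}")
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2
    w = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    w /= w.sum()
    return GaussianTemplate(size=int(size), sigma=float(sigma), weights=w)


def gaussian_denoise(grid: np.ndarray, template: GaussianTemplate) -> np.ndarray:
    """Correlate the grid with the template; borders handled by replication."""
    grid = validate_grid(grid)
    if min(grid.shape) < template.size:
        raise ValidationError(
            f"grid {grid.shape} smaller than template {template.size} x {template.size}"
        )
    return ndimage.correlate(grid, template.weights, mode="nearest")


# ---------------------------------------------------------------------------
# Edge detection and border replication
# ---------------------------------------------------------------------------

_SOBEL_3 = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
# 5x5 Sobel: outer product of the binomial smoother [1 4 6 4 1] with the
# centred derivative [-1 -2 0 2 1].
_SOBEL_5 = np.outer(
    np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
)

SOBEL_KERNELS = {3: _SOBEL_3, 5: _SOBEL_5}


@dataclass(frozen=True)
class EdgeConfig:
    """Sobel stage settings: template size (3 or 5) and the mask threshold
    expressed as a multiple of the mean gradient magnitude."""

    sobel_template: int = 3
    threshold_factor: float = 4.0

    def __post_init__(self):
        if self.sobel_template not in SOBEL_KERNELS:
            raise ValidationError(
                f"sobel_template must be 3 or 5, got {self.sobel_template!r}"
            )
        if not self.threshold_factor > 0:
            raise ValidationError(
                f"threshold_factor must be positive, got {self.threshold_factor!r}"
            )


def edge_enhance(grid: np.ndarray, template_size: int) -> np.ndarray:
    """Replicate the outermost rows/columns outward by ``(template_size-1)/2``.

    This is the border-replication step applied around edge filtering so
    that gradient responses at the frame boundary are not attenuated; after
    filtering, the result is cropped back to the original size.  With
    ``template_size = 1`` the grid is returned unchanged.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.size == 0:
        raise ValidationError(f"expected non-empty 2-D grid, got shape {grid.shape}")
    if not isinstance(template_size, (int, np.integer)) or template_size < 1 or template_size % 2 == 0:
        raise ValidationError(f"template_size must be an odd positive integer, got {template_size!r}")
    pad = (template_size - 1) // 2
    return np.pad(grid, pad, mode="edge")


def sobel_gradient(grid: np.ndarray, cfg: EdgeConfig = EdgeConfig()) -> np.ndarray:
    """Gradient magnitude ``sqrt(gx^2 + gy^2)`` from the configured Sobel
    kernels, with replicated borders."""
    grid = validate_grid(grid)
    k = SOBEL_KERNELS[cfg.sobel_template]
    if min(grid.shape) < cfg.sobel_template:
        raise ValidationError(
            f"grid {grid.shape} smaller than Sobel template {cfg.sobel_template}"
        )
    pad = (cfg.sobel_template - 1) // 2
    padded = edge_enhance(grid, cfg.sobel_template)
    gx = ndimage.correlate(padded, k, mode="constant")
    gy = ndimage.correlate(padded, k.T, mode="constant")
    g = np.hypot(gx, gy)
    return g[pad:-pad, pad:-pad] if pad else g


def sobel_edges(grid: np.ndarray, cfg: EdgeConfig = EdgeConfig()) -> np.ndarray:
    """Binary edge mask: gradient magnitude above ``threshold_factor`` times
    its mean.  A constant grid yields an all-zero mask."""
    g = sobel_gradient(grid, cfg)
    mean = g.mean()
    if mean == 0.0:
        return np.zeros_like(g, dtype=bool)
    return g > cfg.threshold_factor * mean


# ---------------------------------------------------------------------------
# Morphological closing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuringElement:
    """Disc or square neighbourhood for morphological operations."""

    shape: str = "disc"
    radius: int = 3

    def __post_init__(self):
        if self.shape not in ("disc", "square"):
            raise ValidationError(f"shape must be 'disc' or 'square', got {self.shape!r}")
        if not isinstance(self.radius, (int, np.integer)) or self.radius < 1:
            raise ValidationError(f"radius must be an integer >= 1, got {self.radius!r}")

    def footprint(self) -> np.ndarray:
        r = self.radius
        if self.shape == "square":
            return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        ax = np.arange(-r, r + 1)
        return ax[:, None] ** 2 + ax[None, :] ** 2 <= r**2


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce to a boolean 2-D mask, rejecting anything but 0/1 values."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValidationError(f"expected non-empty 2-D mask, got shape {mask.shape}")
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.isin(uniq, (0, 1)).all():
            raise ValidationError("binary mask may contain only 0 and 1")
        mask = mask.astype(bool)
    return mask


def morphological_close(mask: np.ndarray, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Dilation followed by erosion with the structuring element.

    The mask is zero-padded by the element radius before dilating so the
    operation follows infinite-plane set semantics: closing is extensive
    (``close(X) ⊇ X``), idempotent, and increasing, even for foreground
    touching the frame border.
    """
    mask = validate_mask(mask)
    fp = se.footprint()
    r = se.radius
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    dil = ndimage.binary_dilation(padded, structure=fp)
    ero = ndimage.binary_erosion(dil, structure=fp, border_value=0)
    return ero[r:-r, r:-r]


# ---------------------------------------------------------------------------
# Binarisation
# ---------------------------------------------------------------------------

N_BINS = 256


def otsu_threshold(grid: np.ndarray) -> float:
    """Otsu's threshold over 256 histogram bins on [0, 1].

    Values are quantised to 8-bit levels ``k/255``; the returned threshold
    ``t`` maximises the between-class variance of the split
    ``grid <= t`` vs ``grid > t``.  A plateau of equally optimal levels
    (empty bins between two populations) resolves to its midpoint.
    """
    grid = validate_grid(grid)
    levels = np.round(grid * (N_BINS - 1)).astype(np.int64)
    hist = np.bincount(levels.ravel(), minlength=N_BINS).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValidationError(
            "constant grid: Otsu thresholding is undefined; use a fixed threshold"
        )
    p = hist / hist.sum()
    bins = np.arange(N_BINS, dtype=np.float64)
    w0 = np.cumsum(p)[:-1]            # class weight for threshold after bin k
    w1 = 1.0 - w0
    mu0 = np.cumsum(p * bins)[:-1]    # unnormalised class-0 mean
    mu_t = (p * bins).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu0) ** 2 / (w0 * w1)
    var_between[~np.isfinite(var_between)] = -np.inf
    ties = np.flatnonzero(var_between == var_between.max())
    k = int(ties[0] + ties[-1]) // 2
    return k / (N_BINS - 1)


def binarise(
    grid: np.ndarray,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> np.ndarray:
    """Threshold an intensity grid to a boolean foreground mask.

    ``method='otsu'`` picks the 256-bin between-class-variance optimum and
    requires a non-constant grid; ``method='fixed'`` uses
    ``fixed_threshold`` in (0, 1).  Foreground is strictly above threshold.
    """
    grid = validate_grid(grid)
    if method == "otsu":
        t = otsu_threshold(grid)
    elif method == "fixed":
        if fixed_threshold is None or not 0.0 < fixed_threshold < 1.0:
            raise ValidationError(
                f"fixed binarisation needs a threshold in (0, 1), got {fixed_threshold!r}"
            )
        t = float(fixed_threshold)
    else:
        raise ValidationError(f"unknown binarisation method {method!r}")
    return grid > t
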