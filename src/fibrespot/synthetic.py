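"""Seeded laser-spot simulator with known ground-truth anisotropy.

The generator emulates what the transmitted-spot photographs look like: an
elliptical-decay intensity profile (light spreads farther along the fibre
axis), multiplied by unit-mean gamma-distributed speckle (the standard
surrogate for fully developed laser speckle), plus additive Gaussian sensor
noise, clipped and quantised to the red channel of an 8-bit photograph.

Because every iso-intensity contour of the noiseless profile shares one
axis ratio, the simulator provides an exact ground truth for the
orientation statistic: ``(sigma_major / sigma_minor)^2``.

Default geometry is a 1536 x 1536 frame with a minor-axis scale of 200 px —
a spot that fills most of the frame, as the close-up camera photographs do.
The inward-shift step subtracts a fixed pixel distance from both axes, so
its effect on the axis ratio shrinks as the spot grows; a frame-filling
spot keeps the default 20-px shift benign.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DEFAULT_FRAME = 1536
DEFAULT_SIGMA_MINOR = 200.0
DEFAULT_SPECKLE_CONTRAST = 0.3
DEFAULT_BACKGROUND_SD = 0.01

#: Residual green/blue bleed of the red laser on the sensor.
GB_FRACTION = 0.04


@dataclass(frozen=True)
class GroundTruth:
    """True geometry behind a simulated spot."""

    axis_ratio: float
    true_degree_of_orientation: float
    tilt: float


@dataclass(frozen=True)
class SyntheticSpotSpec:
    """Complete description of one simulated spot.

    ``sigma_major`` / ``sigma_minor`` are the e^(-1/2) decay scales (pixels)
    along and across the fibre direction; ``speckle_contrast`` is the
    standard deviation of the unit-mean multiplicative noise; the 3-sigma
    ellipse must fit inside the frame.
    """

    height: int = DEFAULT_FRAME
    width: int = DEFAULT_FRAME
    centre: tuple[float, float] | None = None  # (row, col); None -> frame centre
    sigma_major: float = DEFAULT_SIGMA_MINOR
    sigma_minor: float = DEFAULT_SIGMA_MINOR
    tilt: float = math.radians(25.0)
    amplitude: float = 0.9
    speckle_contrast: float = DEFAULT_SPECKLE_CONTRAST
    background_noise_sd: float = DEFAULT_BACKGROUND_SD
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ValidationError("frame must be at least 16 x 16 pixels")
        if not (self.sigma_major >= self.sigma_minor > 0):
            raise ValidationError(
                f"need sigma_major >= sigma_minor > 0, got "
                f"{self.sigma_major!r}, {self.sigma_minor!r}"
            )
        if not (0.0 < self.amplitude <= 1.0):
            raise ValidationError(f"amplitude must lie in (0, 1], got {self.amplitude!r}")
        if self.speckle_contrast < 0 or self.background_noise_sd < 0:
            raise ValidationError("noise levels must be non-negative")
        cr, cc = self.effective_centre()
        # Half extents of the rotated 3-sigma ellipse along rows/cols.
        st, ct = math.sin(self.tilt), math.cos(self.tilt)
        ext_c = 3.0 * math.hypot(self.sigma_major * ct, self.sigma_minor * st)
        ext_r = 3.0 * math.hypot(self.sigma_major * st, self.sigma_minor * ct)
        if (
            cr - ext_r < 0
            or cr + ext_r > self.height - 1
            or cc - ext_c < 0
            or cc + ext_c > self.width - 1
        ):
            raise ValidationError("3-sigma ellipse of the spot does not fit inside the frame")

    def effective_centre(self) -> tuple[float, float]:
        if self.centre is not None:
            return self.centre
        return ((self.height - 1) / 2.0, (self.width - 1) / 2.0)

    def ground_truth(self) -> GroundTruth:
        ratio = self.sigma_major / self.sigma_minor
        return GroundTruth(
            axis_ratio=ratio, true_degree_of_orientation=ratio**2, tilt=self.tilt
        )


def generate_spot(spec: SyntheticSpotSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one spot photograph; identical spec (incl. seed) gives a
    bit-identical image."""
    rng = np.random.default_rng(spec.seed)
    cr, cc = spec.effective_centre()
    rows = np.arange(spec.height, dtype=np.float64)[:, None] - cr
    cols = np.arange(spec.width, dtype=np.float64)[None, :] - cc
    ct, st = math.cos(spec.tilt), math.sin(spec.tilt)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    intensity = spec.amplitude * np.exp(
        -(u**2 / (2.0 * spec.sigma_major**2) + v**2 / (2.0 * spec.sigma_minor**2))
    )
    if spec.speckle_contrast > 0:
        # Unit-mean gamma noise: shape k = 1/contrast^2 gives sd = contrast.
        k = 1.0 / spec.speckle_contrast**2
        intensity = intensity * rng.gamma(k, 1.0 / k, size=intensity.shape)
    if spec.background_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.background_noise_sd, size=intensity.shape)
    red = np.round(np.clip(intensity, 0.0, 1.0) * 255.0).astype(np.uint8)
    gb = np.round(red * GB_FRACTION).astype(np.uint8)
    image = np.stack([red, gb, gb], axis=-1)
    return image, spec.ground_truth()


def generate_cohort(
    specs: list[tuple[str, SyntheticSpotSpec]],
    replicates: int,
    base_seed: int = 0,
    outdir: str | os.PathLike | None = None,
) -> tuple[list[tuple[str, np.ndarray]], pd.DataFrame]:
    """Simulate ``replicates`` spots per group from per-group templates.

    Replicate ``j`` of group ``i`` uses seed ``base_seed + i*replicates + j``,
    so the cohort is reproducible from ``base_seed`` alone.  When ``outdir``
    is given, PNG images and a ``truth.csv`` table are written there.

    Returns ``(images, truth)`` where ``images`` is a list of
    ``(file name, H x W x 3 array)`` and ``truth`` mirrors the CSV.
    """
    if replicates < 1:
        raise ValidationError(f"replicates must be >= 1, got {replicates!r}")
    labels = [g for g, _ in specs]
    if len(set(labels)) != len(labels):
        dupes = sorted({g for g in labels if labels.count(g) > 1})
        raise ValidationError(f"duplicate group labels: {dupes}")

    images: list[tuple[str, np.ndarray]] = []
    rows = []
    for i, (group, template) in enumerate(specs):
        for j in range(replicates):
            seed = base_seed + i * replicates + j
            spec = replace(template, seed=seed)
            image, truth = generate_spot(spec)
            name = f"{group}_{j:03d}.png"
            images.append((name, image))
            rows.append(
                {
                    "file": name,
                    "group": group,
                    "sigma_major": spec.sigma_major,
                    "sigma_minor": spec.sigma_minor,
                    "tilt_deg": round(math.degrees(spec.tilt), 3),
                    "true_DO": truth.true_degree_of_orientation,
                    "seed": seed,
                }
            )
    truth_table = pd.DataFrame(rows)
    if outdir is not None:
        import imageio.v3 as iio

        os.makedirs(outdir, exist_ok=True)
        for name, image in images:
            iio.imwrite(os.path.join(outdir, name), image)
        truth_table.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    return images, truth_table


def spec_for_orientation(
    true_do: float,
    sigma_minor: float = DEFAULT_SIGMA_MINOR,
    **overrides,
) -> SyntheticSpotSpec:
    """Spec whose ground-truth degree of orientation equals ``true_do``."""
    if true_do < 1.0:
        raise ValidationError(f"degree of orientation cannot be below 1, got {true_do!r}")
    return SyntheticSpotSpec(
        sigma_major=sigma_minor * math.sqrt(true_do), sigma_minor=sigma_minor, **overrides
    )
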