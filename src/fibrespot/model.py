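"""Model/results facade over the measurement pipeline.

``LaserSpotModel`` wraps one photograph plus a :class:`PipelineConfig`;
``fit()`` runs the processing chain and returns the
:class:`~fibrespot.pipeline.OrientationResult`, extended here with a
``summary()`` table and an overlay ``plot()``.  This mirrors the
model-object idiom of statistical packages: construct from data, fit,
inspect the results object.
"""

from __future__ import annotations

import os

import numpy as np

from .image import load_image, validate_image
from .pipeline import OrientationResult, PipelineConfig, run_pipeline
from .synthetic import SyntheticSpotSpec, generate_spot


class OrientationFit:
    """Results wrapper: the fitted ellipse, the statistic, diagnostics."""

    def __init__(self, result: OrientationResult, image: np.ndarray, source: str = ""):
        self.result = result
        self.image = image
        self.source = source

    # Delegate the scalar results.
    @property
    def ellipse(self):
        return self.result.ellipse

    @property
    def degree_of_orientation(self) -> float:
        return self.result.degree_of_orientation

    def summary(self) -> str:
        """Human-readable fit report."""
        el = self.result.ellipse
        lines = [
            "Laser-spot orientation fit",
            "==========================",
            f"source:                 {self.source or '<array>'}",
            f"config digest:          {self.result.config_digest}",
            f"boundary points:        {self.result.boundary_point_count}",
            f"fit RMS distance (px):  {self.result.fit_rms:.3f}",
            f"centre (row, col):      ({el.centre[0]:.2f}, {el.centre[1]:.2f})",
            f"long axis L_L (px):     {el.long_axis:.2f}",
            f"short axis L_S (px):    {el.short_axis:.2f}",
            f"tilt (deg):             {np.degrees(el.tilt):.2f}",
            f"degree of orientation:  {self.result.degree_of_orientation:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the fitted ellipse (and boundary, if kept) on the image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(self.image)
        el = self.result.ellipse
        pts = el.sample(720)
        ax.plot(pts[:, 1], pts[:, 0], "r-", lw=1.5, label="fitted ellipse")
        if self.result.boundary is not None:
            b = self.result.boundary.points
            ax.plot(b[:, 1], b[:, 0], ".", ms=1, color="cyan", label="traced boundary")
        ax.plot(el.centre[1], el.centre[0], "r+", ms=10)
        ax.set_title(f"degree of orientation = {self.degree_of_orientation:.3f}")
        ax.legend(loc="lower right", fontsize="small")
        return ax


class LaserSpotModel:
    """One spot photograph plus a pipeline configuration, ready to fit."""

    def __init__(self, image: np.ndarray, config: PipelineConfig | None = None, source: str = ""):
        self.image = validate_image(image)
        self.config = config or PipelineConfig()
        self.source = source

    @classmethod
    def from_file(cls, path: str | os.PathLike, config: PipelineConfig | None = None):
        return cls(load_image(path), config=config, source=os.fspath(path))

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpotSpec, config: PipelineConfig | None = None):
        image, truth = generate_spot(spec)
        model = cls(image, config=config, source=f"synthetic(seed={spec.seed})")
        model.truth = truth
        return model

    def fit(self, keep_stages: bool = False) -> OrientationFit:
        result = run_pipeline(self.image, self.config, keep_stages=keep_stages)
        return OrientationFit(result, self.image, source=self.source)
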