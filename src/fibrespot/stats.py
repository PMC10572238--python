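"""Verification-layer statistics and pseudocolour rendering.

The optical orientation statistic is validated against the conventional
destructive index for fibrous foods — the *degree of organisation*, the
ratio of transverse to longitudinal shear force from texture analysis —
using per-group summaries (mean, SD, CV, range), mean normalisation of both
series, and Spearman rank correlation.  Pseudocolour maps of the raw spot
render the elliptical outline for qualitative confirmation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ValidationError
from .image import validate_grid


@dataclass(frozen=True)
class ShearMeasurement:
    """One texture-analyser reading (forces in newtons)."""

    sample_id: str
    transverse_force: float
    longitudinal_force: float

    def __post_init__(self):
        if self.transverse_force < 0:
            raise ValidationError("transverse force must be non-negative")
        if not self.longitudinal_force > 0:
            raise ValidationError("longitudinal force must be positive")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    cv_percent: float
    min: float
    max: float


def degree_of_organisation(m: ShearMeasurement) -> float:
    """Transverse / longitudinal shear force; the destructive fibre index."""
    return m.transverse_force / m.longitudinal_force


def coefficient_of_variation(samples: Sequence[float]) -> float:
    """100 * sample SD (n-1 denominator) / mean; requires a positive mean."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValidationError(f"need at least 2 samples, got {x.size}")
    mean = x.mean()
    if not mean > 0:
        raise ValidationError(f"coefficient of variation needs a positive mean, got {mean}")
    return float(100.0 * x.std(ddof=1) / mean)


def mean_normalise(values: Sequence[float]) -> np.ndarray:
    """Map each x to ``(x - mean) / (max - min)``; the output has zero mean."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot normalise an empty sequence")
    rng = x.max() - x.min()
    if rng <= 0:
        raise ValidationError("mean normalisation needs max > min (non-constant input)")
    return (x - x.mean()) / rng


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties), in [-1, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValidationError(f"need at least 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation is undefined for a constant vector")
    r = sps.spearmanr(x, y).statistic
    return float(r)


def summarise_group(group: str, samples: Sequence[float]) -> GroupSummary:
    """Mean, SD, CV and range of one group's measurements."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValidationError(f"group '{group}': need at least 2 samples, got {x.size}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = float(100.0 * sd / mean) if mean > 0 else float("nan")
    return GroupSummary(
        group=group, n=int(x.size), mean=mean, sd=sd, cv_percent=cv,
        min=float(x.min()), max=float(x.max()),
    )


def organisation_table(shear: pd.DataFrame) -> pd.DataFrame:
    """Per-sample degrees of organisation from a shear-force table.

    Expects columns ``group``, ``sample_id``, ``transverse_force_N``,
    ``longitudinal_force_N``; appends a ``degree_of_organisation`` column
    (ratios are computed per sample and only then summarised, matching how
    the group averages of the destructive index are defined).
    """
    required = {"group", "sample_id", "transverse_force_N", "longitudinal_force_N"}
    missing = required - set(shear.columns)
    if missing:
        raise ValidationError(f"shear table missing columns: {sorted(missing)}")
    if (shear["longitudinal_force_N"] <= 0).any():
        raise ValidationError("longitudinal forces must be positive")
    out = shear.copy()
    out["degree_of_organisation"] = (
        out["transverse_force_N"] / out["longitudinal_force_N"]
    )
    return out


def group_summary_table(df: pd.DataFrame, value: str, group: str = "group") -> pd.DataFrame:
    """Stack :func:`summarise_group` over the groups of a tidy table."""
    rows = [
        vars(summarise_group(str(g), sub[value].to_numpy()))
        for g, sub in df.groupby(group, sort=False)
    ]
    return pd.DataFrame(rows)


def pseudocolour_map(grid: np.ndarray, colormap: str = "inferno") -> np.ndarray:
    """False-colour rendering of an intensity grid as an RGB uint8 image.

    The [min, max] intensity range maps linearly onto the colormap's 256
    entries; a constant grid renders as a single colour with a warning.
    """
    import matplotlib

    grid = validate_grid(grid)
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError:
        raise ValidationError(f"unknown colormap {colormap!r}") from None
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        warnings.warn("constant grid: pseudocolour map is a single colour", stacklevel=2)
        idx = np.zeros(grid.shape, dtype=np.int64)
    else:
        idx = np.round((grid - lo) / (hi - lo) * 255.0).astype(np.int64)
    lut = (np.asarray(cmap(np.linspace(0.0, 1.0, 256)))[:, :3] * 255.0).round().astype(np.uint8)
    return lut[idx]
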