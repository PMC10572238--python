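"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: exhaustive search instead of vectorised histogram
algebra, python-set morphology instead of scipy.ndimage, a converged
geometric-distance minimiser instead of the algebraic conic fit, and the
textbook mid-rank formula instead of scipy's Spearman.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def otsu_exhaustive(grid: np.ndarray) -> float:
    """Best threshold k/255 by looping over all 255 candidate splits and
    computing each class's weight and mean from the raw pixel lists."""
    levels = np.round(np.asarray(grid, dtype=float) * 255).astype(int).ravel()
    n = levels.size
    variances = np.full(256, -np.inf)
    for k in range(255):
        c0 = levels[levels <= k]
        c1 = levels[levels > k]
        if c0.size == 0 or c1.size == 0:
            continue
        w0 = c0.size / n
        w1 = c1.size / n
        variances[k] = w0 * w1 * (c0.mean() - c1.mean()) ** 2
    ties = np.flatnonzero(variances == variances.max())
    return (int(ties[0] + ties[-1]) // 2) / 255.0


def _se_offsets(footprint: np.ndarray) -> list[tuple[int, int]]:
    r = (footprint.shape[0] - 1) // 2
    return [(i - r, j - r) for i, j in zip(*np.nonzero(footprint))]


def dilate_set(fg: set, offsets) -> set:
    return {(r + dr, c + dc) for (r, c) in fg for (dr, dc) in offsets}


def erode_set(fg: set, offsets) -> set:
    return {(r, c) for (r, c) in fg if all((r + dr, c + dc) in fg for (dr, dc) in offsets)}


def close_set(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Closing by explicit set algebra on the infinite integer plane,
    cropped back to the mask's frame."""
    offsets = _se_offsets(footprint)
    fg = set(zip(*(arr.tolist() for arr in np.nonzero(mask))))
    closed = erode_set(dilate_set(fg, offsets), offsets)
    out = np.zeros(mask.shape, dtype=bool)
    for r, c in closed:
        if 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]:
            out[r, c] = True
    return out


def _point_ellipse_distances(x, y, cx, cy, a, b, theta, n_grid: int = 256):
    """Exact orthogonal distance from each (x, y) to the ellipse boundary:
    coarse parametric grid to bracket the foot point, then Newton refinement
    of the projection equation (P - E(t)) . E'(t) = 0."""
    ct, st = np.cos(theta), np.sin(theta)
    # work in the ellipse frame
    u = (x - cx) * ct + (y - cy) * st
    v = -(x - cx) * st + (y - cy) * ct
    t = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
    d2 = (u[:, None] - a * np.cos(t)[None, :]) ** 2 + (
        v[:, None] - b * np.sin(t)[None, :]
    ) ** 2
    ti = t[np.argmin(d2, axis=1)]
    for _ in range(8):
        c_, s_ = np.cos(ti), np.sin(ti)
        du = u - a * c_
        dv = v - b * s_
        g = du * a * s_ - dv * b * c_          # -(P-E).E'(t) up to sign
        gp = a * c_ * du + a * s_ * a * s_ + dv * b * s_ + b * c_ * b * c_
        step = np.where(np.abs(gp) > 1e-12, g / gp, 0.0)
        ti = ti - step
    return np.hypot(u - a * np.cos(ti), v - b * np.sin(ti))


def geometric_ellipse_fit(pts_rc: np.ndarray, init: tuple[float, float, float, float, float]):
    """Least-squares minimiser of true point-to-boundary distances.

    ``init`` is (cx, cy, a, b, theta) in x=col, y=row coordinates.
    Returns (cx, cy, a, b, theta) at convergence, axes unsorted.
    """
    x = np.asarray(pts_rc, dtype=float)[:, 1]
    y = np.asarray(pts_rc, dtype=float)[:, 0]

    def resid(p):
        cx, cy, a, b, th = p
        return _point_ellipse_distances(x, y, cx, cy, abs(a), abs(b), th)

    sol = least_squares(resid, x0=np.asarray(init, dtype=float), xtol=1e-12, ftol=1e-12)
    cx, cy, a, b, th = sol.x
    return cx, cy, abs(a), abs(b), th


def spearman_midrank(x, y) -> float:
    """Pearson correlation of mid-ranks, ties averaged, by hand."""

    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(v.size, dtype=float)
        i = 0
        while i < v.size:
            j = i
            while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx = midranks(x)
    ry = midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
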