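"""Boundary extraction and least-squares ellipse fitting.

The cleaned binary spot mask is reduced to an ordered outer boundary
(Moore-neighbour tracing of the largest 8-connected component),
optionally shifted inward by a fixed pixel
distance, and fitted with a direct algebraic least-squares ellipse
(Halir & Flusser's numerically stable formulation of Fitzgibbon's
ellipse-specific conic fit).  The anisotropy statistic is the squared ratio
of the long to the short axis, ``(L_L / L_S)^2 = (a / b)^2``: 1 for an
isotropic (circular) spot, larger for better-aligned fibres.

Coordinates are 0-based ``(row, col)``; the tilt angle of the major axis is
measured from the +col (x) axis toward +row and normalised to [0, pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .preprocess import validate_mask

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order starting due west, (drow, dcol).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass(frozen=True)
class BoundaryPath:
    """Ordered (row, col) pixel coordinates of a traced contour."""

    points: np.ndarray  # (N, 2) int array
    closed: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError(f"boundary points must be (N, 2), got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FittedEllipse:
    """Geometric ellipse parameters; ``a >= b`` are the semi-axes in pixels.

    The reported full axis lengths are ``L_L = 2a`` and ``L_S = 2b``;
    only their ratio enters the orientation statistic.
    """

    centre: tuple[float, float]  # (row, col)
    a: float
    b: float
    tilt: float  # radians in [0, pi)

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValidationError(f"semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.tilt < math.pi):
            raise ValidationError(f"tilt must lie in [0, pi), got {self.tilt}")

    @property
    def long_axis(self) -> float:
        return 2.0 * self.a

    @property
    def short_axis(self) -> float:
        return 2.0 * self.b

    def sample(self, n: int = 360) -> np.ndarray:
        """``n`` points on the ellipse as an (n, 2) array of (row, col)."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        ct, st = np.cos(self.tilt), np.sin(self.tilt)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        col = self.centre[1] + x * ct - y * st
        row = self.centre[0] + x * st + y * ct
        return np.column_stack([row, col])


def degree_of_orientation(ellipse: FittedEllipse) -> float:
    """Squared long/short axis ratio ``(L_L / L_S)^2``; always >= 1."""
    return (ellipse.a / ellipse.b) ** 2


# ---------------------------------------------------------------------------
# Boundary tracing
# ---------------------------------------------------------------------------


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest-area 8-connected foreground component of a mask."""
    mask = validate_mask(mask)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise ValidationError("empty mask: no foreground pixels")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def _moore_trace(comp: np.ndarray) -> np.ndarray:
    """Ordered clockwise outer boundary of one 8-connected component."""
    h, w = comp.shape
    rows, cols = np.nonzero(comp)
    i0 = np.lexsort((cols, rows))[0]
    start = (int(rows[i0]), int(cols[i0]))

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and comp[r, c]

    path = [start]
    cur = start
    back = (start[0], start[1] - 1)  # due-west background by construction
    start_back = back
    limit = 8 * len(rows) + 8
    for _ in range(limit):
        rel = (back[0] - cur[0], back[1] - cur[1])
        i = _MOORE.index(rel)
        nxt = None
        for k in range(1, 9):
            d = (i + k) % 8
            cand = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(*cand):
                nxt = cand
                prev = (cur[0] + _MOORE[(d - 1) % 8][0], cur[1] + _MOORE[(d - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        new_back = prev
        if nxt == start and new_back == start_back:  # Jacob's stopping criterion
            break
        path.append(nxt)
        cur, back = nxt, new_back
    return np.asarray(path, dtype=np.int64)


def trace_outer_boundary(mask: np.ndarray) -> BoundaryPath:
    """Ordered closed outer boundary of the largest foreground component.

    Consecutive points are 8-connected; the trace runs clockwise starting
    from the topmost-leftmost component pixel.
    """
    comp = largest_component(mask)
    pts = _moore_trace(comp)
    if len(pts) < 5:
        raise ValidationError(
            f"largest component has only {len(pts)} boundary pixels; need >= 5 for fitting"
        )
    return BoundaryPath(points=pts, closed=True)


def fill_outer_region(mask: np.ndarray) -> np.ndarray:
    """Largest component with its interior holes filled."""
    return ndimage.binary_fill_holes(largest_component(mask))


def shift_boundary_inward(mask: np.ndarray, offset: int = 20) -> BoundaryPath:
    """Boundary of the filled spot region eroded inward by ``offset`` pixels.

    The largest component's outer contour is filled, the filled region is
    eroded by a Euclidean disc of radius ``offset`` (realised as a
    distance-transform threshold), and the eroded region's outer boundary is
    traced.  ``offset = 0`` reproduces the plain filled-mask trace.
    """
    if not isinstance(offset, (int, np.integer)) or offset < 0:
        raise ValidationError(f"offset must be an integer >= 0, got {offset!r}")
    filled = fill_outer_region(mask)
    if offset > 0:
        dist = ndimage.distance_transform_edt(filled)
        max_feasible = int(np.ceil(dist.max())) - 1
        filled = dist > offset
        if not filled.any():
            raise ValidationError(
                f"inward offset {offset} erodes the region away; "
                f"maximal feasible offset is {max(max_feasible, 0)}"
            )
        filled = largest_component(filled)
    return trace_outer_boundary(filled)


# ---------------------------------------------------------------------------
# Direct least-squares ellipse fitting
# ---------------------------------------------------------------------------


def _conic_to_geometric(coef: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Convert conic ``Ax^2+Bxy+Cy^2+Dx+Ey+F=0`` (x=col, y=row) to
    (centre(row,col), a, b, tilt)."""
    A, B, C, D, E, F = (float(v) for v in coef)
    disc = 4.0 * A * C - B * B
    if disc <= 0:
        raise ValidationError("fitted conic is not an ellipse")
    # Centre from the gradient system [[2A, B], [B, 2C]] @ (cx, cy) = -(D, E).
    cx, cy = np.linalg.solve(np.array([[2.0 * A, B], [B, 2.0 * C]]), -np.array([D, E]))
    m0 = np.array([[F, D / 2.0, E / 2.0], [D / 2.0, A, B / 2.0], [E / 2.0, B / 2.0, C]])
    m1 = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vec = np.linalg.eigh(m1)
    det0, det1 = np.linalg.det(m0), np.linalg.det(m1)
    with np.errstate(invalid="raise"):
        try:
            axes = np.sqrt(-det0 / (det1 * lam))
        except FloatingPointError:
            raise ValidationError("fitted conic is degenerate") from None
    order = np.argsort(axes)[::-1]  # major first (smallest eigenvalue)
    a, b = float(axes[order[0]]), float(axes[order[1]])
    v = vec[:, order[0]]  # (x, y) direction of the major axis
    tilt = math.atan2(v[1], v[0]) % math.pi
    return (float(cy), float(cx)), a, b, tilt


def fit_ellipse_lsq(path: BoundaryPath | np.ndarray) -> FittedEllipse:
    """Direct algebraic least-squares ellipse fit to boundary points.

    Minimises the algebraic distance of the conic over coefficient vectors
    constrained to the ellipse branch (``4AC - B^2 > 0``), using the
    Halir-Flusser block decomposition.  Input coordinates are centred and
    uniformly scaled before solving for numerical conditioning; the
    transform is undone on the returned parameters.
    """
    pts = path.points if isinstance(path, BoundaryPath) else np.asarray(path)
    pts = np.asarray(pts, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected (N, 2) boundary points, got shape {pts.shape}")
    if len(pts) < 5:
        raise ValidationError(f"need >= 5 boundary points to fit an ellipse, got {len(pts)}")
    y = pts[:, 0]
    x = pts[:, 1]
    xm, ym = x.mean(), y.mean()
    scale = max(x.std(), y.std())
    if scale <= 0:
        raise ValidationError("boundary points are collinear or coincident")
    xs = (x - xm) / scale
    ys = (y - ym) / scale

    d1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    d2 = np.column_stack([xs, ys, np.ones_like(xs)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_block = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError:
        raise ValidationError("rank-deficient boundary scatter; cannot fit ellipse") from None
    m = s1 + s2 @ t_block
    # Premultiply by inv(C1) for the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]].
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    w, v = np.linalg.eig(m)
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    ok = np.where(np.isreal(w) & (cond > 0))[0]
    if len(ok) == 0:
        raise ValidationError("no ellipse solution for these boundary points")
    a1 = np.real(v[:, ok[0]])
    if a1[0] < 0:
        a1 = -a1
    coef = np.concatenate([a1, t_block @ a1])

    centre_s, a_s, b_s, tilt = _conic_to_geometric(coef)
    centre = (centre_s[0] * scale + ym, centre_s[1] * scale + xm)
    return FittedEllipse(centre=centre, a=a_s * scale, b=b_s * scale, tilt=tilt)


def fit_rms_distance(ellipse: FittedEllipse, path: BoundaryPath | np.ndarray) -> float:
    """RMS first-order (Sampson) point-to-ellipse distance, in pixels.

    A cheap goodness-of-fit diagnostic: the algebraic residual of each
    boundary point normalised by the local conic gradient.
    """
    pts = path.points if isinstance(path, BoundaryPath) else np.asarray(path)
    pts = np.asarray(pts, dtype=np.float64)
    ct, st = math.cos(ellipse.tilt), math.sin(ellipse.tilt)
    dy = pts[:, 0] - ellipse.centre[0]
    dx = pts[:, 1] - ellipse.centre[1]
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    f = (u / ellipse.a) ** 2 + (v / ellipse.b) ** 2 - 1.0
    grad = 2.0 * np.hypot(u / ellipse.a**2, v / ellipse.b**2)
    grad = np.where(grad > 0, grad, np.inf)
    return float(np.sqrt(np.mean((f / grad) ** 2)))
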