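"""Subpixel xy localization by weighted least-squares line intersection.

Each selected gradient pixel defines a line through its position along its
gradient direction; for a radially symmetric particle those lines all pass
near the center, which is recovered as the point minimizing the weighted
sum of squared perpendicular distances to the lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError, NoParticleError
from .gradients import GradientField, local_gradients, magnitude, shift_min

__all__ = ["LocalizationResult", "intersect_lines", "localize"]

#: condition number above which the 2x2 normal matrix is declared singular
COND_LIMIT = 1e8


@dataclass
class LocalizationResult:
    """Subpixel particle center in source-image pixel coordinates.

    ``residual`` is the root-mean-square perpendicular distance of the used
    gradient lines to the center; ``z_value`` is filled by the axial module
    when a z-metric is computed.
    """

    x: float
    y: float
    n_lines: int
    residual: float
    z_value: float | None = None
    frame_index: int | None = None

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


def intersect_lines(
    points: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Weighted least-squares intersection of 2D lines.

    Line *i* passes through ``points[i]`` with (unit) direction
    ``directions[i]``.  Returns the point ``c`` minimizing
    ``sum_i w_i * d_perp(c, line_i)^2`` via the 2x2 normal equations
    ``sum_i w_i (I - n_i n_i^T) c = sum_i w_i (I - n_i n_i^T) p_i``,
    together with the (unweighted) rms perpendicular distance.

    Raises :class:`InsufficientDataError` for fewer than two lines and
    :class:`DegenerateGeometryError` when all lines are (near-)parallel.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if p.shape[0] < 2:
        raise InsufficientDataError(f"need at least 2 lines, got {p.shape[0]}")
    if p.shape != d.shape or p.shape[1] != 2:
        raise ValueError("points and directions must both be (n, 2)")
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length direction vector")
    d = d / norms[:, None]
    if weights is None:
        w = np.ones(len(p))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")

    # I - n n^T for unit n = (nx, ny) is [[ny^2, -nx*ny], [-nx*ny, nx^2]]
    nx, ny = d[:, 0], d[:, 1]
    q11 = w * ny * ny
    q12 = -w * nx * ny
    q22 = w * nx * nx
    A = np.array([[q11.sum(), q12.sum()], [q12.sum(), q22.sum()]])
    b = np.array([
        (q11 * p[:, 0] + q12 * p[:, 1]).sum(),
        (q12 * p[:, 0] + q22 * p[:, 1]).sum(),
    ])
    if not np.all(np.isfinite(A)) or np.linalg.cond(A) > COND_LIMIT:
        raise DegenerateGeometryError("gradient lines are (near-)parallel; center undetermined")
    c = np.linalg.solve(A, b)

    rel = c[None, :] - p
    perp = rel - d * np.sum(rel * d, axis=1)[:, None]
    residual = float(np.sqrt(np.mean(np.sum(perp**2, axis=1))))
    return c, residual


def localize(
    image: np.ndarray,
    r: float,
    threshold_frac: float = 1 / 1.4,
    precomputed=None,
    uniform_weights: bool = False,
    field: GradientField | None = None,
    normalize: bool = True,
) -> LocalizationResult:
    """Localize a single radially symmetric particle to subpixel accuracy.

    Pipeline: local gradients (radius ``r``) → magnitude threshold at
    ``threshold_frac`` of the maximum → weighted least-squares intersection
    of the surviving gradient lines.  Lines are weighted by gradient
    magnitude unless ``uniform_weights`` is set.  The center is reported in
    source-image pixel coordinates (x = column, y = row).

    ``normalize`` shifts the image minimum to zero first (the convention
    used for noisy camera frames; exactly neutral for the center estimate,
    see :func:`logradient.gradients.shift_min`).  A precomputed gradient
    ``field`` may be supplied to skip recomputation.
    """
    if field is None:
        img = shift_min(image) if normalize else image
        fld = local_gradients(img, r, precomputed=precomputed)
    else:
        fld = field
    mf = magnitude(fld, threshold_frac)
    rows, cols = np.nonzero(mf.selected)
    if rows.size == 0:
        raise NoParticleError("no gradient pixels above threshold")
    pts = np.column_stack([cols + fld.origin_col, rows + fld.origin_row]).astype(float)
    dirs = np.column_stack([fld.gx[rows, cols], fld.gy[rows, cols]])
    w = None if uniform_weights else mf.mag[rows, cols]
    center, residual = intersect_lines(pts, dirs, w)
    return LocalizationResult(
        x=float(center[0]), y=float(center[1]), n_lines=int(rows.size), residual=residual
    )
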