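"""Multi-particle detection and trajectory linking.

Thresholded gradient pixels are grouped with DBSCAN (each particle's
gradient ring is a dense blob of selected pixels); every cluster is then
localized independently by least-squares intersection of only its member
lines.  Per-frame localizations are linked into trajectories with a greedy
mutual-nearest-neighbor assignment suitable for online use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import DegenerateGeometryError, InsufficientDataError, InvalidParameterError
from .gradients import local_gradients, magnitude, shift_min
from .localize import LocalizationResult, intersect_lines

__all__ = ["ParticleCluster", "Trajectory", "detect_particles", "link_trajectories"]


@dataclass
class ParticleCluster:
    """One detected particle: its selected gradient pixels and localization."""

    member_pixels: np.ndarray  # (n, 2) gradient-raster (row, col)
    localization: LocalizationResult


@dataclass
class Trajectory:
    """Time-ordered localizations of one particle identity."""

    particle_id: int
    points: list = field(default_factory=list)  # [(frame_index, LocalizationResult), ...]
    gaps: int = 0

    @property
    def frames(self) -> list:
        return [f for f, _ in self.points]

    def __len__(self) -> int:
        return len(self.points)


def detect_particles(
    image: np.ndarray,
    r: float,
    threshold_frac: float = 1 / 1.3,
    eps: float | None = None,
    min_samples: int = 5,
    precomputed=None,
    normalize: bool = True,
    min_spread: float | None = None,
    max_residual_ratio: float = 0.15,
) -> list[ParticleCluster]:
    """Detect and localize every particle in a frame.

    Selected gradient pixels are clustered by DBSCAN (radius ``eps``,
    default ``r/2``; density ``min_samples``); sub-density groups are
    discarded as noise, and each surviving cluster is localized from its
    member gradient lines only.  An empty list is a valid result.

    Two geometric filters reject clusters of correlated noise excursions
    (the window-averaged gradient field is smooth, so noise peaks come in
    small blobs too): a real particle's selected pixels ring it at roughly
    the window scale, so clusters with rms spatial spread below
    ``min_spread`` (default ``0.45*r``) are dropped, as are clusters whose
    gradient lines do not converge (intersection residual larger than
    ``max_residual_ratio`` times the spread — a particle's lines all point
    at one center with residual/spread well under 0.1, noise lines point
    nowhere with ratios several times higher).  Degenerate (all-parallel)
    clusters are dropped for the same reason.
    """
    if eps is None:
        eps = r / 2.0
    if not (eps > 0):
        raise InvalidParameterError("eps must be positive")
    if min_samples < 2:
        raise InvalidParameterError("min_samples must be >= 2")

    fld = local_gradients(shift_min(image) if normalize else image, r, precomputed=precomputed)
    mf = magnitude(fld, threshold_frac)
    rows, cols = np.nonzero(mf.selected)
    if rows.size == 0:
        return []
    coords = np.column_stack([cols, rows]).astype(float)  # (x, y)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)

    clusters: list[ParticleCluster] = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        sel = labels == lab
        rr, cc = rows[sel], cols[sel]
        pts = np.column_stack([cc + fld.origin_col, rr + fld.origin_row]).astype(float)
        dirs = np.column_stack([fld.gx[rr, cc], fld.gy[rr, cc]])
        w = mf.mag[rr, cc]
        try:
            center, residual = intersect_lines(pts, dirs, w)
        except (DegenerateGeometryError, InsufficientDataError):
            continue
        spread = float(np.sqrt(np.mean(np.sum((pts - pts.mean(axis=0)) ** 2, axis=1))))
        if spread < (min_spread if min_spread is not None else 0.45 * r):
            continue
        if residual > max_residual_ratio * spread:
            continue
        clusters.append(
            ParticleCluster(
                member_pixels=np.column_stack([rr, cc]),
                localization=LocalizationResult(
                    x=float(center[0]), y=float(center[1]),
                    n_lines=int(rr.size), residual=residual,
                ),
            )
        )
    return clusters


def link_trajectories(
    per_frame: list[list[LocalizationResult]],
    max_link_distance: float,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Link per-frame localizations into trajectories.

    Greedy mutual-nearest assignment: at each frame the globally closest
    (trajectory, detection) pair within ``max_link_distance`` is linked
    first, then the next closest among the remainder, and so on — a pair
    linked this way is mutually nearest among unassigned candidates.
    Trajectories unmatched for more than ``max_gap`` consecutive frames are
    closed; unmatched detections always start new trajectories, so every
    localization belongs to exactly one trajectory.
    """
    if max_link_distance <= 0:
        raise InvalidParameterError("max_link_distance must be positive")
    trajectories: list[Trajectory] = []
    active: list[Trajectory] = []
    next_id = 0

    for f, detections in enumerate(per_frame):
        detections = list(detections)
        # retire trajectories whose gap budget is exhausted
        still = []
        for tr in active:
            if f - tr.points[-1][0] - 1 > max_gap:
                trajectories.append(tr)
            else:
                still.append(tr)
        active = still

        unmatched = list(range(len(detections)))
        if active and unmatched:
            last = np.array([[tr.points[-1][1].x, tr.points[-1][1].y] for tr in active])
            det = np.array([[d.x, d.y] for d in detections])
            dist = np.linalg.norm(last[:, None, :] - det[None, :, :], axis=2)
            dist = dist.copy()
            free_tr = set(range(len(active)))
            free_det = set(unmatched)
            while free_tr and free_det:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                if not np.isfinite(dist[i, j]) or dist[i, j] > max_link_distance:
                    break
                tr = active[i]
                gap_here = f - tr.points[-1][0] - 1
                tr.gaps += gap_here
                tr.points.append((f, detections[j]))
                free_tr.discard(i)
                free_det.discard(j)
                dist[i, :] = np.inf
                dist[:, j] = np.inf
            unmatched = sorted(free_det)

        for j in unmatched:
            tr = Trajectory(particle_id=next_id, points=[(f, detections[j])])
            next_id += 1
            active.append(tr)

    trajectories.extend(active)
    trajectories.sort(key=lambda t: t.particle_id)
    return trajectories
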