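"""Axial (z) metrics and calibration curves.

Three scalar metrics, each strictly monotonic in axial position over its
working range, are converted to nanometers through a per-particle
calibration curve (look-up table or linear fit):

* **brightfield** — half-difference of local-gradient sums: split ``gx``
  into columns right/left of the particle center and take the difference of
  their sums; likewise for ``gy`` split by rows; average the two.  The ring
  structure of a defocused bead changes sign through focus, so this
  difference tracks defocus.
* **astigmatism** — the thresholded gradient lines are split into
  top/bottom and left/right half-planes about the center; each half's
  least-squares intersection gives a point, the two point pairs form a
  vertical and a horizontal axis, and the signed axis-length difference
  ``L_v - L_h`` crosses zero in focus and flips sign with the 90-degree
  major-axis flip of the astigmatic PSF.
* **double-helix** — the lobe-axis orientation from intensity-weighted
  central second moments of the thresholded gradient magnitude,
  ``theta = 0.5*atan2(2*mu11, mu20 - mu02)`` in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import (
    CalibrationRangeError,
    ExtrapolationError,
    InsufficientDataError,
    InvalidParameterError,
    NoParticleError,
    OutOfBoundsError,
    UndefinedOrientationError,
)
from .gradients import GradientField, MagnitudeField, local_gradients, magnitude, shift_min
from .localize import LocalizationResult, intersect_lines, localize

__all__ = [
    "CalibrationCurve",
    "z_value_brightfield",
    "z_value_astigmatism",
    "z_value_doublehelix",
    "build_calibration",
    "apply_calibration",
]


def z_value_brightfield(fld: GradientField, center) -> float:
    """Half-difference brightfield z-metric at a given particle center.

    ``center`` is (x, y) in source-image pixel coordinates.  Columns of
    ``gx`` strictly right of the (rounded) center contribute positively,
    strictly left negatively; rows of ``gy`` below/above likewise; the
    center row/column is excluded from both halves.  The gx and gy
    differences are averaged.
    """
    cx = float(center[0]) - fld.origin_col
    cy = float(center[1]) - fld.origin_row
    nrows, ncols = fld.shape
    if not (0 <= cx <= ncols - 1 and 0 <= cy <= nrows - 1):
        raise OutOfBoundsError(f"center {tuple(center)} outside gradient raster")
    jc = int(round(cx))
    ic = int(round(cy))
    cols = np.arange(ncols)
    rows = np.arange(nrows)
    zx = fld.gx[:, cols > jc].sum() - fld.gx[:, cols < jc].sum()
    zy = fld.gy[rows > ic, :].sum() - fld.gy[rows < ic, :].sum()
    return 0.5 * (zx + zy)


def z_value_astigmatism(fld: GradientField, mag: MagnitudeField, center) -> float:
    """Split-gradient-axes astigmatism z-metric (signed axis difference).

    Selected gradient lines are split into half-planes above/below and
    left/right of ``center``; each subset's least-squares intersection
    yields a point, and the two point pairs form a vertical and a
    horizontal axis.  Returns the signed difference of the axis lengths
    projected on their own axes,
    ``L_v - L_h = (P_bottom - P_top)·ŷ - (P_right - P_left)·x̂``:
    zero for a round PSF, sign-flipped under a 90-degree rotation, and —
    because the projections are signed — strictly monotonic through focus
    where the intersection points pass through each other (an unsigned
    norm folds there and loses the sign of the ellipticity).
    """
    rows, cols = np.nonzero(mag.selected)
    if rows.size == 0:
        raise NoParticleError("no gradient pixels above threshold")
    x = cols + fld.origin_col
    y = rows + fld.origin_row
    pts = np.column_stack([x, y]).astype(float)
    dirs = np.column_stack([fld.gx[rows, cols], fld.gy[rows, cols]])
    w = mag.mag[rows, cols]
    cx, cy = float(center[0]), float(center[1])

    def half(sel, name):
        if np.count_nonzero(sel) < 2:
            raise InsufficientDataError(f"fewer than 2 gradient lines in {name} half-plane")
        c, _ = intersect_lines(pts[sel], dirs[sel], w[sel])
        return c

    p_top = half(y < cy, "top")
    p_bottom = half(y > cy, "bottom")
    p_left = half(x < cx, "left")
    p_right = half(x > cx, "right")
    L_v = float(p_bottom[1] - p_top[1])
    L_h = float(p_right[0] - p_left[0])
    return L_v - L_h


def z_value_doublehelix(
    image: np.ndarray,
    r: float = 15.0,
    threshold_frac: float = 1 / 1.3,
    binarize: bool = False,
    precomputed=None,
    normalize: bool = False,
) -> float:
    """Double-helix lobe-axis angle (degrees) from central moments.

    Computes local gradients with a large window ``r`` (which merges the
    two lobes into one elongated structure), thresholds the gradient
    magnitude, and takes the orientation of the principal axis of the
    magnitude-weighted central second moments:
    ``theta = 0.5*atan2(2*mu11, mu20-mu02) * 180/pi`` in (-90, 90],
    in image coordinates (x right, y down).  ``binarize`` switches the
    moment weights from magnitude values to 0/1.

    ``normalize`` defaults to False: double-helix frames carry their own
    optical background, which keeps the window masses stable; min-shifting
    it away would let far-field PSF tails saturate the magnitude raster.
    """
    fld = local_gradients(shift_min(image) if normalize else image, r, precomputed=precomputed)
    mf = magnitude(fld, threshold_frac)
    rows, cols = np.nonzero(mf.selected)
    if rows.size == 0:
        raise NoParticleError("no gradient pixels above threshold")
    w = np.ones(rows.size) if binarize else mf.mag[rows, cols]
    W = w.sum()
    xbar = (w * cols).sum() / W
    ybar = (w * rows).sum() / W
    dx = cols - xbar
    dy = rows - ybar
    mu20 = (w * dx * dx).sum()
    mu02 = (w * dy * dy).sum()
    mu11 = (w * dx * dy).sum()
    aniso = np.hypot(2 * mu11, mu20 - mu02)
    if aniso < 1e-9 * (mu20 + mu02 + 1e-300):
        raise UndefinedOrientationError("isotropic moment tensor; lobe angle undefined")
    theta = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    return float(theta)


@dataclass
class CalibrationCurve:
    """Ordered (stage z [nm], metric value) pairs with an inversion strategy.

    ``mode='lut'`` inverts by piecewise-linear interpolation over the
    calibration nodes; ``mode='linear'`` fits ``value = slope*z +
    intercept`` by ordinary least squares and inverts the fit.  Metric
    values must be strictly monotonic in z over the calibrated range.
    """

    stage_z: np.ndarray
    values: np.ndarray
    mode: str = "lut"
    fit_slope: float | None = None
    fit_intercept: float | None = None
    metric: str = ""
    params: dict = dc_field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "stage_z": np.asarray(self.stage_z).tolist(),
            "values": np.asarray(self.values).tolist(),
            "mode": self.mode,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "metric": self.metric,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            stage_z=np.asarray(d["stage_z"], dtype=float),
            values=np.asarray(d["values"], dtype=float),
            mode=d["mode"],
            fit_slope=d["fit_slope"],
            fit_intercept=d["fit_intercept"],
            metric=d.get("metric", ""),
            params=d.get("params", {}),
        )


_METRICS = ("brightfield", "astig", "dh")


def _metric_value(
    image: np.ndarray,
    metric: str,
    r: float,
    threshold_frac: float,
    center=None,
    precomputed=None,
    normalize: bool | None = None,
) -> float:
    """Compute one z-metric value on one image (localizing if needed).

    ``normalize`` defaults per metric: the brightfield half-difference is a
    sum over gradient values whose scale depends on the image baseline, so
    its images are taken as-is (brightfield frames carry their own large
    background); the astigmatism and double-helix metrics are geometric and
    get the min-shift normalization that stabilizes low-background
    fluorescence frames.
    """
    if normalize is None:
        normalize = metric == "astig"
    if metric == "dh":
        return z_value_doublehelix(image, r, threshold_frac,
                                   precomputed=precomputed, normalize=normalize)
    fld = local_gradients(shift_min(image) if normalize else image, r, precomputed=precomputed)
    mf = magnitude(fld, threshold_frac)
    if center is None:
        loc = localize(image, r, threshold_frac, field=fld)
        center = (loc.x, loc.y)
    if metric == "brightfield":
        return z_value_brightfield(fld, center)
    if metric == "astig":
        return z_value_astigmatism(fld, mf, center)
    raise InvalidParameterError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def stack_centers(stack, r: float, threshold_frac: float, precomputed=None) -> np.ndarray:
    """Median (x, y) center of a fixed particle across a z-stack.

    Planes where localization fails (e.g. at a brightfield contrast
    crossing the particle vanishes) are skipped; the median over the
    remaining planes gives a robust shared center for calibration.
    """
    centers = []
    for img in stack:
        try:
            loc = localize(img, r, threshold_frac, precomputed=precomputed)
        except Exception:
            continue
        centers.append((loc.x, loc.y))
    if not centers:
        raise NoParticleError("no plane of the stack could be localized")
    return np.median(np.asarray(centers), axis=0)


def build_calibration(
    stack,
    stage_z,
    metric: str = "brightfield",
    r: float = 10.0,
    threshold_frac: float = 1 / 1.4,
    mode: str = "lut",
    center=None,
    precomputed=None,
    normalize: bool | None = None,
) -> CalibrationCurve:
    """Build a calibration curve from a z-stack with known stage positions.

    The metric is evaluated on every plane; for the center-referenced
    metrics (brightfield, astigmatism) a shared robust center is estimated
    from the whole stack unless ``center`` is given — the calibration
    particle is a fixed fiducial, so one center serves all planes.
    Double-helix angles are unwrapped (period 180 deg) against neighboring
    planes before the monotonicity check.

    Raises :class:`CalibrationRangeError` for fewer than 3 planes or
    non-monotonic metric values (naming the offending interval).
    """
    stage_z = np.asarray(stage_z, dtype=float)
    stack = list(stack)
    if len(stack) != len(stage_z):
        raise InvalidParameterError("stack and stage_z lengths differ")
    if len(stack) < 3:
        raise CalibrationRangeError(f"need at least 3 planes, got {len(stack)}")
    if np.any(np.diff(stage_z) <= 0):
        raise CalibrationRangeError("stage_z must be strictly increasing")
    if metric not in _METRICS:
        raise InvalidParameterError(f"unknown metric {metric!r}; expected one of {_METRICS}")

    if metric != "dh" and center is None:
        center = stack_centers(stack, r, threshold_frac, precomputed=precomputed)

    values = np.array(
        [
            _metric_value(img, metric, r, threshold_frac, center=center,
                          precomputed=precomputed, normalize=normalize)
            for img in stack
        ]
    )
    if metric == "dh":
        values = np.unwrap(values, period=180.0)

    d = np.diff(values)
    if not (np.all(d > 0) or np.all(d < 0)):
        trend = 1.0 if d.sum() >= 0 else -1.0
        i = int(np.nonzero(d * trend <= 0)[0][0])
        raise CalibrationRangeError(
            f"metric not strictly monotonic between z={stage_z[i]:g} and z={stage_z[i + 1]:g} nm"
        )

    curve = CalibrationCurve(
        stage_z=stage_z,
        values=values,
        mode=mode,
        metric=metric,
        params={"r": r, "threshold_frac": threshold_frac,
                "center": None if center is None else [float(center[0]), float(center[1])]},
    )
    if mode == "linear":
        slope, intercept = np.polyfit(stage_z, values, 1)
        curve.fit_slope = float(slope)
        curve.fit_intercept = float(intercept)
    elif mode != "lut":
        raise InvalidParameterError(f"mode must be 'lut' or 'linear', got {mode!r}")
    return curve


def apply_calibration(curve: CalibrationCurve, value: float) -> float:
    """Invert a calibration curve: metric value → stage z in nm.

    Look-up mode uses piecewise-linear inverse interpolation and refuses to
    extrapolate; linear-fit mode inverts the fitted line for any value.
    """
    if curve.mode == "linear":
        if curve.fit_slope is None or curve.fit_slope == 0:
            raise InvalidParameterError("linear calibration has no usable fit")
        return float((value - curve.fit_intercept) / curve.fit_slope)
    v = np.asarray(curve.values, dtype=float)
    z = np.asarray(curve.stage_z, dtype=float)
    if v[0] > v[-1]:
        v, z = v[::-1], z[::-1]
    if value < v[0] or value > v[-1]:
        raise ExtrapolationError(
            f"value {value:g} outside calibration range [{v[0]:g}, {v[-1]:g}]"
        )
    return float(np.interp(value, v, z))
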