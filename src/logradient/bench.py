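"""Accuracy benchmark harness and baseline localizers.

Reproduces the synthetic accuracy-vs-SNR protocols: seeded image sets per
SNR level (same set for every localizer), Euclidean localization error
against ground truth, and the odd/even axial-calibration protocol (build
the calibration from every odd stack plane, score prediction error on the
even planes).

The baselines — thresholded intensity centroid, adjacent-pixel gradients,
and a nonlinear 2D Gaussian fit — exist for comparison only; the
local-gradient localizer is the method under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .axial import CalibrationCurve, _metric_value, apply_calibration, stack_centers
from .errors import NoParticleError
from .gradients import precompute_transforms, shift_min
from .localize import intersect_lines, localize
from .synthetic import NoiseModel, add_noise, render_gaussian_spot

__all__ = [
    "BenchmarkSpec",
    "run_xy_benchmark",
    "baseline_centroid",
    "baseline_adjacent_gradient",
    "baseline_gaussian_fit",
    "odd_even_axial_protocol",
    "DEFAULT_SNR_LEVELS",
]

#: default 12-level SNR grid spanning the tested extremes (2 … 200)
DEFAULT_SNR_LEVELS = (2, 3, 4, 5, 7, 10, 15, 20, 30, 50, 100, 200)


@dataclass
class BenchmarkSpec:
    """Accuracy-vs-SNR benchmark configuration.

    Error is the Euclidean distance between predicted and true center, in
    pixels, averaged over ``images_per_level`` random placements per SNR.
    """

    snr_levels: tuple = DEFAULT_SNR_LEVELS
    images_per_level: int = 20
    shape: tuple = (100, 100)
    sigma: float = 5.0  # spot width matched to the r=12 window, as the method prescribes
    r: float = 12.0
    threshold_frac: float = 1 / 1.3
    seed: int = 0
    margin: float = 20.0  # particle placement margin from the frame edge


def baseline_centroid(image: np.ndarray, threshold_frac: float = 0.5) -> tuple[float, float]:
    """Thresholded intensity-weighted centroid (the classical baseline).

    Selects pixels ``>= threshold_frac * max`` and returns their
    intensity-weighted mean position.  Biased toward the frame interior
    for particles near an edge; raises :class:`NoParticleError` on a
    uniform image.
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        raise NoParticleError("uniform image; no particle to localize")
    img = img - img.min()
    thr = threshold_frac * img.max()
    sel = img >= thr
    w = img[sel] - thr  # threshold-subtracted weights reduce truncation bias
    rows, cols = np.nonzero(sel)
    if w.sum() <= 0:
        raise NoParticleError("nothing above threshold")
    return float((w * cols).sum() / w.sum()), float((w * rows).sum() / w.sum())


def baseline_adjacent_gradient(
    image: np.ndarray, threshold_frac: float = 1 / 1.4
) -> tuple[float, float]:
    """Radial-symmetry-style localizer: adjacent-pixel gradients.

    Gradients are central differences between adjacent pixels (no window
    averaging), fed to the same least-squares line-intersection backend.
    Comparator for the noise-amplification behavior of fixed minimal
    kernels.
    """
    img = shift_min(image)
    gy, gx = np.gradient(img)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak <= 0:
        raise NoParticleError("flat image; no gradients")
    sel = mag >= threshold_frac * peak
    rows, cols = np.nonzero(sel)
    pts = np.column_stack([cols, rows]).astype(float)
    dirs = np.column_stack([gx[sel], gy[sel]])
    center, _ = intersect_lines(pts, dirs, mag[sel])
    return float(center[0]), float(center[1])


def baseline_gaussian_fit(image: np.ndarray, init=None) -> tuple[float, float]:
    """Nonlinear least-squares 2D Gaussian fit (amplitude, center, width,
    background), termination tolerance 1e-4.  Initialized from the
    thresholded centroid unless ``init`` is given."""
    img = np.asarray(image, dtype=float)
    if init is None:
        init = baseline_centroid(img)
    rows, cols = img.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    lo, hi = img.min(), img.max()
    # wide initial sigma keeps the basin of attraction broad for off inits
    p0 = np.array([hi - lo, init[0], init[1], min(rows, cols) / 4.0, lo])

    def resid(p):
        a, x0, y0, s, b = p
        return (b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) - img).ravel()

    sol = least_squares(resid, p0, xtol=1e-4, ftol=1e-4, gtol=1e-4)
    if not sol.success:
        raise NoParticleError("Gaussian fit did not converge")
    return float(sol.x[1]), float(sol.x[2])


_LOCALIZERS = {
    "log": lambda img, spec: (lambda L: (L.x, L.y))(
        localize(img, spec.r, spec.threshold_frac)
    ),
    "centroid": lambda img, spec: baseline_centroid(img),
    "radial": lambda img, spec: baseline_adjacent_gradient(img, spec.threshold_frac),
    "gauss": lambda img, spec: baseline_gaussian_fit(img),
}


def run_xy_benchmark(spec: BenchmarkSpec, localizers=("log",)) -> pd.DataFrame:
    """Mean xy-localization error per SNR level for each localizer.

    The same seeded image set (random subpixel positions, Gaussian spots,
    additive noise at the level's SNR) is used for every localizer.
    Localization failures are counted in ``n_fail`` and excluded from the
    mean rather than silently averaged.
    """
    rows_out = []
    for snr in spec.snr_levels:
        rng = np.random.default_rng([spec.seed, int(round(snr * 1000))])
        images = []
        for _ in range(spec.images_per_level):
            x0 = rng.uniform(spec.margin, spec.shape[1] - 1 - spec.margin)
            y0 = rng.uniform(spec.margin, spec.shape[0] - 1 - spec.margin)
            img = render_gaussian_spot(spec.shape, x0, y0, spec.sigma)
            img = add_noise(img, NoiseModel(snr=snr), int(rng.integers(2**31)))
            images.append((img, x0, y0))
        for name in localizers:
            fn = _LOCALIZERS[name]
            errs, fails = [], 0
            for img, x0, y0 in images:
                try:
                    x, y = fn(img, spec)
                    errs.append(float(np.hypot(x - x0, y - y0)))
                except Exception:
                    fails += 1
            rows_out.append(
                {
                    "snr": snr,
                    "localizer": name,
                    "mean_error_px": float(np.mean(errs)) if errs else np.nan,
                    "n_images": spec.images_per_level,
                    "n_fail": fails,
                }
            )
    return pd.DataFrame(rows_out)


def odd_even_axial_protocol(
    stack,
    stage_z,
    metric: str,
    r: float,
    threshold_frac: float,
    normalize: bool | None = None,
) -> dict:
    """Odd/even split axial-accuracy protocol on a z-stack.

    Every odd plane (1st, 3rd, …) builds a look-up-table calibration;
    every even plane is scored: the metric value is inverted through the
    calibration and compared with the true stage position.  The particle
    is a fixed fiducial, so one robust shared center (median of per-plane
    localizations over the calibration planes) serves every plane.

    Returns a dict with ``mean_abs_error_nm``, ``max_abs_error_nm``,
    ``errors_nm``, and the calibration curve.
    """
    stage_z = np.asarray(stage_z, dtype=float)
    stack = list(stack)
    if normalize is None:
        normalize = metric == "astig"
    pc = precompute_transforms(stack[0].shape, r)
    center = None
    if metric != "dh":
        center = stack_centers(stack[::2], r, threshold_frac, precomputed=pc)

    values = np.array(
        [
            _metric_value(img, metric, r, threshold_frac, center=center,
                          precomputed=pc, normalize=normalize)
            for img in stack
        ]
    )
    if metric == "dh":
        values = np.unwrap(values, period=180.0)

    cal = CalibrationCurve(
        stage_z=stage_z[0::2], values=values[0::2], mode="lut", metric=metric,
        params={"r": r, "threshold_frac": threshold_frac},
    )
    errors = []
    for z_true, v in zip(stage_z[1::2], values[1::2]):
        z_hat = apply_calibration(cal, v)
        errors.append(abs(z_hat - z_true))
    errors = np.asarray(errors)
    return {
        "mean_abs_error_nm": float(errors.mean()),
        "max_abs_error_nm": float(errors.max()),
        "errors_nm": errors,
        "calibration": cal,
        "center": center,
    }
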