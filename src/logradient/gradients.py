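"""Local-gradient (LoG) fields.

The local gradient at a pixel is the intensity-weighted centroid of all
pixels within a radius ``r`` of it, expressed relative to the window
center.  Sliding that circular window over the image yields two rasters
``gx`` and ``gy`` — the horizontal and vertical centroid coordinates —
which for a radially symmetric particle form a vector field whose lines
all point through the particle center.

Both a direct sliding-window path and an FFT-convolution path are
provided; they agree to high precision and the FFT path supports a
precomputed-transform cache for repeated calls on same-shaped images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft
from scipy import signal

from .errors import InvalidCacheError, InvalidParameterError, SizeError

__all__ = [
    "CircularKernel",
    "GradientField",
    "MagnitudeField",
    "make_kernel",
    "local_gradients",
    "precompute_transforms",
    "magnitude",
]

# kernels with side <= this are correlated directly; larger ones go through FFT
_DIRECT_K_MAX = 7


@dataclass(frozen=True)
class CircularKernel:
    """Circular sliding-window mask and its signed pixel offsets.

    ``K = 2*floor(r) + 1`` so the window is odd-sided and centered on a
    pixel; ``mask`` is 1 inside radius ``r`` of the window center.
    """

    r: float
    K: int
    mask: np.ndarray
    offset_x: np.ndarray
    offset_y: np.ndarray


@dataclass(frozen=True)
class GradientField:
    """Paired gx/gy rasters with geometry tying them to source coordinates.

    Gradient pixel ``(row, col)`` corresponds to source pixel
    ``(row + origin_row, col + origin_col)``; x is column, y is row,
    both 0-based with pixel centers at integer coordinates.
    """

    gx: np.ndarray
    gy: np.ndarray
    origin_row: int
    origin_col: int
    r: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.gx.shape


@dataclass(frozen=True)
class MagnitudeField:
    """Euclidean norm of a gradient field plus a relative-threshold mask."""

    mag: np.ndarray
    threshold_frac: float
    selected: np.ndarray = field(repr=False)


def shift_min(image: np.ndarray) -> np.ndarray:
    """Shift an image so its minimum is zero.

    The centroid-based gradients are exactly invariant to brightness
    scaling and the least-squares center to constant offsets, so this
    normalization costs nothing statistically — but it guarantees a
    non-negative image, which keeps window masses positive and the
    centroid bound |g| <= r valid on noisy low-background data (additive
    noise otherwise drives the local mass of empty regions through zero).
    """
    image = np.asarray(image, dtype=float)
    return image - image.min()


def make_kernel(r: float) -> CircularKernel:
    """Build the circular window of radius ``r`` (side ``K = 2*floor(r)+1``).

    Raises :class:`InvalidParameterError` for non-positive or non-finite r.
    """
    if not np.isfinite(r) or r <= 0:
        raise InvalidParameterError(f"window radius must be positive and finite, got {r!r}")
    K = 2 * int(np.floor(r)) + 1
    c = (K - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(K), np.arange(K))
    offset_x = jj - c
    offset_y = ii - c
    dist = np.hypot(offset_x, offset_y)
    mask = (dist <= r + 1e-12).astype(float)
    return CircularKernel(r=float(r), K=K, mask=mask, offset_x=offset_x, offset_y=offset_y)


class _TransformCache:
    """Precomputed real FFTs of the three correlation kernels.

    Opaque to callers; created by :func:`precompute_transforms` and consumed
    by :func:`local_gradients`.  Tied to one (image shape, r) pair.
    """

    def __init__(self, image_shape: tuple[int, int], r: float):
        kern = make_kernel(r)
        m, n = int(image_shape[0]), int(image_shape[1])
        if m < kern.K or n < kern.K:
            raise SizeError(
                f"image shape {image_shape} is smaller than the {kern.K}x{kern.K} kernel"
            )
        self.image_shape = (m, n)
        self.r = float(r)
        self.kernel = kern
        self.fshape = (
            _fft.next_fast_len(m + kern.K - 1),
            _fft.next_fast_len(n + kern.K - 1),
        )
        # correlation == convolution with the flipped kernel
        def _rfft(k: np.ndarray) -> np.ndarray:
            return np.fft.rfft2(k[::-1, ::-1], self.fshape)

        self.F_den = _rfft(kern.mask)
        self.F_num_x = _rfft(kern.mask * kern.offset_x)
        self.F_num_y = _rfft(kern.mask * kern.offset_y)

    def correlate_valid(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m, n = image.shape
        K = self.kernel.K
        F = np.fft.rfft2(image, self.fshape)
        sl = (slice(K - 1, m), slice(K - 1, n))
        num_x = np.fft.irfft2(F * self.F_num_x, self.fshape)[sl]
        num_y = np.fft.irfft2(F * self.F_num_y, self.fshape)[sl]
        den = np.fft.irfft2(F * self.F_den, self.fshape)[sl]
        return num_x, num_y, den


def precompute_transforms(image_shape: tuple[int, int], r: float) -> _TransformCache:
    """Precompute kernel Fourier transforms for repeated same-shape images.

    The cache is a pure optimization: :func:`local_gradients` with and
    without it agree to floating tolerance.
    """
    return _TransformCache(image_shape, r)


def local_gradients(
    image: np.ndarray,
    r: float,
    precomputed: _TransformCache | None = None,
    support_floor: float = 0.01,
) -> GradientField:
    """Compute the local-gradient field of a 2D image.

    For each valid window position, ``gx`` / ``gy`` are the x/y coordinates
    of the intensity-weighted centroid of the masked window relative to its
    center::

        gx = sum(window * mask * offset_x) / sum(window * mask)

    Windows with zero total intensity get gradient (0, 0); more generally,
    windows carrying less than ``support_floor`` of the maximal window mass
    are treated as empty — the centroid of a PSF's far tail is numerically
    defined but meaningless, and on an image whose background is ~0 those
    tail windows would otherwise saturate the magnitude raster.  On frames
    with an appreciable background every window clears the floor and the
    rasters cover the plain centroid definition.  The output rasters cover
    the full valid-correlation region, ``(m-K+1, n-K+1)``, with origin
    offset ``(K-1)/2``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError(f"image must be 2D, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise InvalidParameterError("image contains non-finite values")

    if precomputed is not None:
        if precomputed.image_shape != image.shape or precomputed.r != float(r):
            raise InvalidCacheError(
                f"cache built for shape {precomputed.image_shape}, r={precomputed.r}; "
                f"got shape {image.shape}, r={r}"
            )
        kern = precomputed.kernel
        num_x, num_y, den = precomputed.correlate_valid(image)
    else:
        kern = make_kernel(r)
        m, n = image.shape
        if m < kern.K or n < kern.K:
            raise SizeError(f"image shape {image.shape} smaller than {kern.K}x{kern.K} kernel")
        if kern.K <= _DIRECT_K_MAX:
            num_x = signal.correlate(image, kern.mask * kern.offset_x, mode="valid", method="direct")
            num_y = signal.correlate(image, kern.mask * kern.offset_y, mode="valid", method="direct")
            den = signal.correlate(image, kern.mask, mode="valid", method="direct")
        else:
            num_x, num_y, den = _TransformCache(image.shape, r).correlate_valid(image)

    # zero/low-support windows -> gradient (0, 0); the 1e-12 term keeps FFT
    # round-off on a black region from blowing up even with a zero floor
    den_peak = np.abs(den).max()
    tol = max(1e-12 * max(den_peak, 1.0), support_floor * den_peak)
    safe = np.abs(den) > tol
    gx = np.zeros_like(den)
    gy = np.zeros_like(den)
    np.divide(num_x, den, out=gx, where=safe)
    np.divide(num_y, den, out=gy, where=safe)

    origin = (kern.K - 1) // 2
    return GradientField(gx=gx, gy=gy, origin_row=origin, origin_col=origin, r=float(r))


def magnitude(fld: GradientField, threshold_frac: float) -> MagnitudeField:
    """Euclidean norm of the gradient field with relative thresholding.

    ``selected`` marks pixels with ``mag >= threshold_frac * max(mag)``;
    an all-zero field selects nothing.  ``threshold_frac`` must lie in
    (0, 1] — it is the reciprocal of the divisor notation (a cutoff of
    "1/1.4 of the maximum" is ``threshold_frac = 1/1.4``).
    """
    if not (0.0 < threshold_frac <= 1.0) or not np.isfinite(threshold_frac):
        raise InvalidParameterError(f"threshold_frac must be in (0, 1], got {threshold_frac!r}")
    mag = np.hypot(fld.gx, fld.gy)
    peak = mag.max() if mag.size else 0.0
    # gradients are centroid offsets in pixels; a peak below 1e-9 px is
    # numerical residue of a flat image, not signal
    if peak <= 1e-9:
        selected = np.zeros_like(mag, dtype=bool)
    else:
        selected = mag >= threshold_frac * peak
    return MagnitudeField(mag=mag, threshold_frac=float(threshold_frac), selected=selected)
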