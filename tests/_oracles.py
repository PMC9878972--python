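"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's convolution / linear-algebra code
paths: the gradient oracle slides an explicit window with Python loops,
and the intersection oracle scans the weighted perpendicular-distance
objective on a dense grid.
"""

import numpy as np


def sliding_window_gradients(img: np.ndarray, r: float):
    """Direct per-pixel windowed-centroid gradients (nested loops)."""
    K = 2 * int(np.floor(r)) + 1
    c = (K - 1) // 2
    m, n = img.shape
    gx = np.zeros((m - K + 1, n - K + 1))
    gy = np.zeros_like(gx)
    inside = [
        (a, b)
        for a in range(K)
        for b in range(K)
        if np.hypot(b - c, a - c) <= r + 1e-12
    ]
    for i in range(m - K + 1):
        for j in range(n - K + 1):
            sw = sx = sy = 0.0
            for a, b in inside:
                v = img[i + a, j + b]
                sw += v
                sx += v * (b - c)
                sy += v * (a - c)
            if abs(sw) > 0:
                gx[i, j] = sx / sw
                gy[i, j] = sy / sw
    return gx, gy


def grid_search_intersection(points, directions, weights, center_guess, span=2.0, step=0.01):
    """Minimize sum_i w_i * d_perp(c, line_i)^2 on a dense grid."""
    p = np.asarray(points, float)
    d = np.asarray(directions, float)
    d = d / np.linalg.norm(d, axis=1)[:, None]
    w = np.asarray(weights, float)
    xs = np.arange(center_guess[0] - span, center_guess[0] + span + step / 2, step)
    ys = np.arange(center_guess[1] - span, center_guess[1] + span + step / 2, step)
    best, best_val = None, np.inf
    for y in ys:
        c = np.column_stack([xs, np.full_like(xs, y)])
        rel = c[:, None, :] - p[None, :, :]
        t = np.einsum("ijk,jk->ij", rel, d)
        perp = rel - t[:, :, None] * d[None, :, :]
        val = (w[None, :] * np.sum(perp**2, axis=2)).sum(axis=1)
        k = int(np.argmin(val))
        if val[k] < best_val:
            best_val = float(val[k])
            best = (float(xs[k]), float(y))
    return np.array(best)
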