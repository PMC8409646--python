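"""Exact Euclidean distance transform of a contour pixel set.

The cost map assigns every grid cell the exact minimum *squared* Euclidean
distance to the nearest contour pixel — zero exactly on the contour. The
squared distances are integers (sums of two integer squares), which is what
makes the cumulative-histogram area curve exact: every achievable dilation
radius appears as the square root of an attained cost value.

The transform is computed by the two-pass separable lower-envelope
algorithm: a column-wise pass finds the nearest contour row per column,
then a row-wise pass minimizes ``(j - k)^2 + g^2`` over the column
distances via the lower envelope of parabolas. The result is exact, not an
approximation, and is verified against a brute-force nearest-contour scan
in the test suite.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .errors import DataError

_INF = float(1 << 52)


@njit(cache=True)
def _edt2d_squared(mask):  # pragma: no cover - exercised via edt_squared
    nrow, ncol = mask.shape
    # Pass 1: per column, distance (in rows) to nearest contour pixel.
    g = np.empty((nrow, ncol), np.float64)
    for j in range(ncol):
        g[0, j] = 0.0 if mask[0, j] else _INF
        for i in range(1, nrow):
            g[i, j] = 0.0 if mask[i, j] else min(g[i - 1, j] + 1.0, _INF)
        for i in range(nrow - 2, -1, -1):
            if g[i + 1, j] + 1.0 < g[i, j]:
                g[i, j] = g[i + 1, j] + 1.0
    # Pass 2: per row, 1D squared-distance transform of f(k) = g[i, k]^2
    # by the lower envelope of the parabolas (x - k)^2 + f(k).
    out = np.empty((nrow, ncol), np.int64)
    v = np.empty(ncol, np.int64)
    z = np.empty(ncol + 1, np.float64)
    f = np.empty(ncol, np.float64)
    for i in range(nrow):
        for j in range(ncol):
            fj = g[i, j]
            f[j] = fj * fj if fj < _INF else _INF
        k = 0
        v[0] = 0
        z[0] = -np.inf
        z[1] = np.inf
        for q in range(1, ncol):
            s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2.0 * q - 2.0 * v[k])
            while s <= z[k]:
                k -= 1
                s = ((f[q] + q * q) - (f[v[k]] + v[k] * v[k])) / (2.0 * q - 2.0 * v[k])
            k += 1
            v[k] = q
            z[k] = s
            z[k + 1] = np.inf
        k = 0
        for j in range(ncol):
            while z[k + 1] < j:
                k += 1
            d = j - v[k]
            out[i, j] = np.int64(d * d + f[v[k]])
    return out


def edt_squared(
    contour: np.ndarray,
    shape: tuple[int, int],
    max_r2: int | None = None,
) -> np.ndarray:
    """Exact squared EDT of a contour pixel set over a grid.

    Parameters
    ----------
    contour : (n, 2) integer array
        (row, col) coordinates of contour pixels, all inside ``shape``.
    shape : (nrow, ncol)
        Grid dimensions.
    max_r2 : int, optional
        Cap: values above it are clipped to ``max_r2``.

    Returns
    -------
    ndarray of int64, shape ``shape``
        Minimum squared Euclidean distance to the nearest contour pixel;
        0 exactly on contour pixels.
    """
    pts = np.asarray(contour)
    if pts.size == 0:
        raise DataError("contour is empty")
    pts = np.atleast_2d(pts).astype(np.int64)
    nrow, ncol = shape
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() >= nrow
        or pts[:, 1].max() >= ncol
    ):
        raise DataError("contour pixels fall outside the grid")
    mask = np.zeros(shape, dtype=np.bool_)
    mask[pts[:, 0], pts[:, 1]] = True
    cost = _edt2d_squared(mask)
    if max_r2 is not None:
        np.minimum(cost, np.int64(max_r2), out=cost)
    return cost
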