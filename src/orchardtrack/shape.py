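"""Hu-moment shape dissimilarity for filled contours.

Moments are computed *analytically* from the polygon boundary (triangle
decomposition against the origin, exact simplex integrals), so the seven
Hu invariants are exactly invariant under translation, rotation, and
uniform scaling of the vertex list — no rasterization error.
"""

from __future__ import annotations

from math import comb, factorial
from typing import Sequence

import numpy as np

__all__ = [
    "polygon_raw_moments",
    "polygon_central_moments",
    "polygon_hu_moments",
    "shape_dissimilarity",
]

_MOMENT_ORDERS = [(p, q) for p in range(4) for q in range(4) if p + q <= 3]


def _as_vertex_arrays(contour: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(contour, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("contour must be a sequence of >=3 (x, y) vertices")
    return arr[:, 0], arr[:, 1]


def polygon_raw_moments(contour: Sequence[tuple[float, float]]) -> dict[tuple[int, int], float]:
    """Exact raw geometric moments m_pq (p+q <= 3) of the filled polygon.

    Decomposes the polygon into signed triangles (origin, v_i, v_{i+1});
    over each triangle the monomial integral has the closed form
    2A * sum_{k,l} C(p,k) C(q,l) x1^k x2^{p-k} y1^l y2^{q-l}
    * (k+l)! (p+q-k-l)! / (p+q+2)!.
    """
    vx, vy = _as_vertex_arrays(contour)
    x1, y1 = vx, vy
    x2, y2 = np.roll(vx, -1), np.roll(vy, -1)
    cross = x1 * y2 - x2 * y1  # 2 * signed triangle area

    m = {key: 0.0 for key in _MOMENT_ORDERS}
    for p, q in _MOMENT_ORDERS:
        total = np.zeros_like(cross)
        for k in range(p + 1):
            for l in range(q + 1):
                coeff = (
                    comb(p, k)
                    * comb(q, l)
                    * factorial(k + l)
                    * factorial(p + q - k - l)
                    / factorial(p + q + 2)
                )
                total += coeff * x1**k * x2 ** (p - k) * y1**l * y2 ** (q - l)
        m[(p, q)] = float(np.sum(cross * total))
    if m[(0, 0)] < 0:  # orientation-normalize: treat area as positive
        m = {key: -val for key, val in m.items()}
    return m


def polygon_central_moments(
    contour: Sequence[tuple[float, float]],
) -> dict[tuple[int, int], float]:
    """Central moments mu_pq, computed by shifting vertices to the centroid."""
    raw = polygon_raw_moments(contour)
    if raw[(0, 0)] == 0.0:
        raise ValueError("degenerate contour: zero area")
    cx = raw[(1, 0)] / raw[(0, 0)]
    cy = raw[(0, 1)] / raw[(0, 0)]
    vx, vy = _as_vertex_arrays(contour)
    shifted = np.column_stack([vx - cx, vy - cy])
    return polygon_raw_moments(shifted)


def polygon_hu_moments(contour: Sequence[tuple[float, float]]) -> np.ndarray:
    """The seven Hu invariant moments of the filled contour."""
    mu = polygon_central_moments(contour)
    mu00 = mu[(0, 0)]
    eta = {
        (p, q): mu[(p, q)] / mu00 ** (1.0 + (p + q) / 2.0)
        for p, q in _MOMENT_ORDERS
        if p + q >= 2
    }
    n20, n02, n11 = eta[(2, 0)], eta[(0, 2)], eta[(1, 1)]
    n30, n03 = eta[(3, 0)], eta[(0, 3)]
    n21, n12 = eta[(2, 1)], eta[(1, 2)]

    s1 = n30 + n12
    s2 = n21 + n03
    d1 = n30 - 3.0 * n12
    d2 = 3.0 * n21 - n03

    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4.0 * n11**2
    h3 = d1**2 + d2**2
    h4 = s1**2 + s2**2
    h5 = d1 * s1 * (s1**2 - 3.0 * s2**2) + d2 * s2 * (3.0 * s1**2 - s2**2)
    h6 = (n20 - n02) * (s1**2 - s2**2) + 4.0 * n11 * s1 * s2
    h7 = d2 * s1 * (s1**2 - 3.0 * s2**2) - d1 * s2 * (3.0 * s1**2 - s2**2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def shape_dissimilarity(
    contour_a: Sequence[tuple[float, float]],
    contour_b: Sequence[tuple[float, float]],
    eps: float = 1e-12,
) -> float:
    """Sum_i |1/m_i(A) - 1/m_i(B)| with m_i = sign(h_i) * log10|h_i|.

    Smaller means more similar; 0 for identical shapes. Terms where either
    shape's |h_i| falls below ``eps`` are skipped pairwise (they carry no
    stable log magnitude).
    """
    hu_a = polygon_hu_moments(contour_a)
    hu_b = polygon_hu_moments(contour_b)
    total = 0.0
    for ha, hb in zip(hu_a, hu_b):
        if abs(ha) <= eps or abs(hb) <= eps:
            continue
        ma = np.sign(ha) * np.log10(abs(ha))
        mb = np.sign(hb) * np.log10(abs(hb))
        total += abs(1.0 / ma - 1.0 / mb)
    return float(total)
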