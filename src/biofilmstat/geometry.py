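"""Spherocylinder contact geometry.

Rod-shaped cells are modelled as spherocylinders: a core axis segment of
length ``L - w`` (pole-to-pole length minus diameter) swept by a sphere of
radius ``w/2``. The surface separation between two cells is then the minimal
distance between their axis segments minus the mean diameter; a negative
separation means steric overlap.

All routines are vectorized over pair arrays so the simulator and the packing
generator can evaluate thousands of candidate contacts per call.
"""

from __future__ import annotations

import numpy as np

__all__ = ["segment_closest_points", "pair_separation"]

_EPS = 1e-12


def _dot(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...i->...", a, b)


def segment_closest_points(
    pa: np.ndarray,
    ua: np.ndarray,
    ea: np.ndarray,
    pb: np.ndarray,
    ub: np.ndarray,
    eb: np.ndarray,
    iterations: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Closest points between segments ``pa + s*ua`` (|s|<=ea) and ``pb + t*ub``.

    Solves the box-constrained quadratic by the unconstrained solution followed
    by alternating coordinate clamping (monotone for this convex problem; the
    iteration count is overkill for all but near-parallel corner cases).

    Returns ``(s, t, dvec, dist)`` where ``dvec`` points from the closest point
    on B to the closest point on A.
    """
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    ua, ub = np.asarray(ua, float), np.asarray(ub, float)
    ea = np.asarray(ea, float)
    eb = np.asarray(eb, float)
    w0 = pa - pb
    b = _dot(ua, ub)
    da = _dot(ua, w0)
    db = _dot(ub, w0)
    den = 1.0 - b * b
    s = np.where(den > _EPS, (b * db - da) / np.where(den > _EPS, den, 1.0), 0.0)
    s = np.clip(s, -ea, ea)
    for _ in range(iterations):
        t = np.clip(b * s + db, -eb, eb)
        s = np.clip(b * t - da, -ea, ea)
    t = np.clip(b * s + db, -eb, eb)
    dvec = w0 + s[..., None] * ua - t[..., None] * ub
    dist = np.linalg.norm(dvec, axis=-1)
    return s, t, dvec, dist


def pair_separation(
    pa: np.ndarray,
    ua: np.ndarray,
    la: np.ndarray,
    pb: np.ndarray,
    ub: np.ndarray,
    lb: np.ndarray,
    width: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Surface separation delta and contact frame for cell pairs.

    ``la``/``lb`` are pole-to-pole lengths; the axis half-length is
    ``(L - w)/2``. delta < 0 means the spherocylinders overlap sterically.

    Returns ``(delta, normal, s, t, dist)``: the unit contact normal points
    from B toward A; ``s``/``t`` locate the contact points on each axis. For
    coincident axis points (dist == 0) the normal falls back deterministically
    to a direction perpendicular to A's axis.
    """
    w = np.asarray(width, float)
    ea = np.maximum(np.asarray(la, float) - w, 0.0) / 2.0
    eb = np.maximum(np.asarray(lb, float) - w, 0.0) / 2.0
    s, t, dvec, dist = segment_closest_points(pa, ua, ea, pb, ub, eb)
    delta = dist - w

    safe = dist > _EPS
    normal = np.where(safe[..., None], dvec / np.where(safe, dist, 1.0)[..., None], 0.0)
    if not np.all(safe):
        # fixed fallback axis: z unless the cell axis is nearly vertical
        fb = np.cross(ua, np.broadcast_to([0.0, 0.0, 1.0], np.shape(ua)))
        nb = np.linalg.norm(fb, axis=-1)
        fb2 = np.cross(ua, np.broadcast_to([1.0, 0.0, 0.0], np.shape(ua)))
        use2 = nb < 1e-6
        fb = np.where(use2[..., None], fb2, fb)
        fb = fb / np.linalg.norm(fb, axis=-1, keepdims=True)
        normal = np.where(safe[..., None], normal, fb)
    return delta, normal, s, t, dist
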