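"""Geometric primitives: segment distances, line fits, azimuth convention.

Azimuth convention (shared by whip and hand orientation metrics): the angle
of a direction's horizontal projection measured from "straight backward"
(pointing from the body directly away from the target), positive toward the
participant's right, in (-180, 180] degrees.  With the lab frame x toward
the target and y to the participant's left, a direction ``v`` has azimuth
``atan2(-v_y, -v_x)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_segment_distance",
    "polyline_segment_distance",
    "fit_line_svd",
    "azimuth_of_direction",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate for a well-defined result (e.g. line fit)."""


def segment_segment_distance(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Minimum distance between segments [p1,p2] and [q1,q2], vectorized.

    All inputs broadcast as (..., 3); returns (...).  Standard closest-point
    parametrization with clamping; robust to degenerate (point) segments.
    """
    p1, p2, q1, q2 = (np.asarray(a, dtype=float) for a in (p1, p2, q1, q2))
    d1 = p2 - p1
    d2 = q2 - q1
    r = p1 - q1
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    f = np.sum(d2 * r, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    denom = a * e - b * b
    eps = 1e-15
    # initial s on the infinite lines, clamped
    s = np.where(denom > eps, np.clip((b * f - c * e) / np.where(denom > eps, denom, 1.0), 0.0, 1.0), 0.0)
    t = np.where(e > eps, (b * s + f) / np.where(e > eps, e, 1.0), 0.0)
    # re-clamp t, then recompute s for clamped t
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(
        t_cl != t,
        np.clip((t_cl * b - c) / np.where(a > eps, a, 1.0), 0.0, 1.0),
        s,
    )
    # degenerate target segment: closest point of [p1,p2] to the point q1
    s = np.where(e <= eps, np.clip(-c / np.where(a > eps, a, 1.0), 0.0, 1.0), s)
    s = np.where(a > eps, s, 0.0)
    t = t_cl
    closest_p = p1 + s[..., None] * d1
    closest_q = q1 + t[..., None] * d2
    return np.linalg.norm(closest_p - closest_q, axis=-1)


def polyline_segment_distance(
    polyline: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Minimum distance between a polyline and a segment, per frame.

    ``polyline`` is (frames, k, 3) with k >= 2 vertices in chain order;
    ``q1``/``q2`` are (frames, 3).  Returns (frames,), NaN where any vertex
    involved in every candidate segment is NaN.
    """
    polyline = np.asarray(polyline, dtype=float)
    k = polyline.shape[1]
    dists = np.stack(
        [
            segment_segment_distance(polyline[:, i], polyline[:, i + 1], q1, q2)
            for i in range(k - 1)
        ],
        axis=0,
    )
    allnan = np.isnan(dists).all(axis=0)
    safe = np.where(np.isnan(dists), np.inf, dists)
    out = safe.min(axis=0)
    out[allnan] = np.nan
    return out


def fit_line_svd(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through 3-D points via SVD.

    Returns (centroid, unit direction).  Raises
    :class:`DegenerateGeometryError` when the points are nearly coincident
    or the principal direction is not dominant.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[~np.isnan(pts).any(axis=1)]
    if len(pts) < 3:
        raise DegenerateGeometryError("need >=3 valid points for a line fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.linalg.norm(centered) < 1e-9:
        raise DegenerateGeometryError("points nearly coincident")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise DegenerateGeometryError("degenerate point cloud")
    return centroid, vt[0]


def azimuth_of_direction(direction: np.ndarray) -> float:
    """Azimuth in degrees of a direction's horizontal projection.

    0 deg = straight backward (away from the target), positive = toward the
    participant's right; result in (-180, 180].
    """
    v = np.asarray(direction, dtype=float)
    if np.hypot(v[0], v[1]) < 1e-12:
        raise DegenerateGeometryError("direction has no horizontal component")
    ang = np.degrees(np.arctan2(-v[1], -v[0]))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
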