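"""Least-squares recovery of the rotational center from minor-axis lines.

Stacking the n normal-form line equations gives an overdetermined system

    [a_1 b_1; ...; a_n b_n] (x, y)^T = (c_1, ..., c_n)^T

whose least-squares solution — computed through the SVD pseudo-inverse —
is the estimated ocular rotational center point (ORCP).  When the lines
genuinely concur, the solution is their common point.  The module also
provides the angular residual used as the RANSAC consensus test and the
orbit-radius estimator derived from the foreshortening geometry
``d = R sin(RAE)``, ``cos(RAE) = b/a``.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .line_extraction import MinorAxisLine
from .simulate import PupilEllipse

__all__ = [
    "intersect_lines",
    "intersect_coefficients",
    "angular_residual",
    "estimate_radius",
]

#: relative singular-value cutoff for rank decisions in the pseudo-inverse
SVD_RCOND = 1e-12

#: inliers with sin(RAE) below this take no part in the radius estimate
#: (the per-sample radius d / sin(RAE) is ill-conditioned near frontal gaze)
MIN_SIN_RAE = 0.1


def intersect_coefficients(ab: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares intersection from raw stacked coefficients.

    ``ab`` is (n, 2) of line normals, ``c`` the (n,) right-hand sides.
    Solves via the SVD pseudo-inverse with relative cutoff ``SVD_RCOND``.
    """
    ab = np.asarray(ab, dtype=float)
    c = np.asarray(c, dtype=float)
    if ab.shape[0] < 2:
        raise ValueError("need at least two lines to intersect")
    if np.linalg.matrix_rank(ab, tol=SVD_RCOND * np.linalg.norm(ab, 2)) < 2:
        raise ValueError("no unique intersection: lines are mutually parallel")
    sol = np.linalg.pinv(ab, rcond=SVD_RCOND) @ c
    return float(sol[0]), float(sol[1])


def intersect_lines(lines: Sequence[MinorAxisLine]) -> tuple[float, float]:
    """Least-squares common point of a set of minor-axis lines.

    Exact (to machine precision) when all lines share a point; otherwise
    the point minimizing the sum of squared residuals of the stacked
    system.  Invariant to line order and to sign flips of any line's
    coefficient triple.
    """
    ab = np.array([[ln.a, ln.b] for ln in lines], dtype=float)
    c = np.array([ln.c for ln in lines], dtype=float)
    return intersect_coefficients(ab, c)


def angular_residual(e: PupilEllipse, point: tuple[float, float]) -> float:
    """Unsigned angle (degrees, in [0, 90]) between the ellipse's minor-axis
    direction and the direction from its center to ``point``.

    This is the consensus metric: an ideal observation of an eye rotating
    about ``point`` has residual zero.  Lines are undirected, so the angle
    is taken modulo 180 and folded into [0, 90].  A point coinciding with
    the center lies on the line trivially; the residual is defined as 0.
    """
    if e.degenerate:
        raise ValueError("angular residual undefined for a degenerate ellipse")
    vx = point[0] - e.cx
    vy = point[1] - e.cy
    if np.hypot(vx, vy) < 1e-9:
        return 0.0
    theta = np.deg2rad(e.minor_axis_angle)
    ux, uy = np.cos(theta), np.sin(theta)
    # atan2(|cross|, |dot|) stays accurate for near-zero angles, where the
    # arccos of a near-unit cosine would lose ~8 digits
    cross = abs(ux * vy - uy * vx)
    dot = abs(ux * vx + uy * vy)
    return float(np.rad2deg(np.arctan2(cross, dot)))


def estimate_radius(
    inliers: Sequence[PupilEllipse],
    orcp: tuple[float, float],
    min_sin_rae: float = MIN_SIN_RAE,
) -> float:
    """Orbit radius from the sine-wave relation of ideal projections.

    For each inlier, ``cos(RAE) = b/a`` gives the gaze deviation and the
    center's distance from the rotational center satisfies
    ``d = R sin(RAE)``; the per-sample estimates ``R_i = d_i / sin(RAE_i)``
    are averaged over inliers with ``sin(RAE_i) >= min_sin_rae``.
    """
    estimates = []
    for e in inliers:
        if e.degenerate or e.semi_major == 0:
            continue
        cos_rae = min(e.semi_minor / e.semi_major, 1.0)
        sin_rae = np.sqrt(1.0 - cos_rae * cos_rae)
        if sin_rae < min_sin_rae:
            continue
        d = np.hypot(e.cx - orcp[0], e.cy - orcp[1])
        estimates.append(d / sin_rae)
    if not estimates:
        raise ValueError("radius undetermined: no admissible inlier")
    return float(np.mean(estimates))
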