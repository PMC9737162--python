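"""Ellipse parameter recovery from 2-D contours.

Fits the general conic ``Ax^2 + Bxy + Cy^2 + Dx + Ey + F = 0`` to contour
points by the numerically stable direct least-squares method with the
ellipse constraint ``4AC - B^2 = 1`` (Halir & Flusser's partitioned form of
Fitzgibbon's fit), then converts the conic to the geometric parameters the
downstream estimator consumes: center, semi-axes and the orientation of
the *minor* axis.  Reporting the minor-axis angle (rather than the
conventional major-axis angle) matches its role in gaze geometry, where it
equals the rotation direction angle of the eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CIRCULARITY_THRESHOLD, Contour, PupilEllipse

__all__ = ["ConicCoefficients", "fit_conic", "conic_to_ellipse"]


@dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients of Ax^2 + Bxy + Cy^2 + Dx + Ey + F = 0, unit-normalized.

    The ellipse discriminant B^2 - 4AC < 0 is enforced at construction.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        v = np.array([self.A, self.B, self.C, self.D, self.E, self.F])
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("all-zero conic")
        if self.B * self.B - 4.0 * self.A * self.C >= 0:
            raise ValueError("conic is not an ellipse (discriminant >= 0)")
        v = v / norm
        # canonical overall sign: quadratic part positive definite
        if v[0] + v[2] < 0:
            v = -v
        for name, val in zip("ABCDEF", v):
            object.__setattr__(self, name, float(val))

    def residuals(self, points: np.ndarray) -> np.ndarray:
        """Algebraic residual of the conic at each point."""
        x, y = np.asarray(points, dtype=float).T
        return (
            self.A * x * x
            + self.B * x * y
            + self.C * y * y
            + self.D * x
            + self.E * y
            + self.F
        )


def fit_conic(contour: Contour) -> ConicCoefficients:
    """Direct least-squares ellipse-specific conic fit to a contour.

    Minimizes the algebraic residual subject to ``4AC - B^2 = 1``, which
    guarantees the solution is an ellipse.  Coordinates are centered on
    the contour mean before fitting for numerical conditioning and the
    conic is translated back afterwards.

    Raises
    ------
    ValueError
        If the points are collinear or otherwise admit no ellipse.
    """
    pts = contour.points
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T

    d1 = np.column_stack([x * x, x * y, y * y])  # quadratic design block
    d2 = np.column_stack([x, y, np.ones_like(x)])  # linear design block
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("no ellipse fit: degenerate contour") from exc
    m = s1 + s2 @ t
    # premultiply by the inverse of the constraint matrix [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(m)
    # the ellipse eigenpair is provably real; drop numerically complex ones
    eigval, eigvec = np.real(eigval), np.real(eigvec)
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    valid = np.flatnonzero((cond > 0) & np.isfinite(eigval))
    if valid.size == 0:
        raise ValueError("no ellipse fit: points do not determine an ellipse")
    a1 = eigvec[:, valid[0]]
    coeffs = np.concatenate([a1, t @ a1])

    # undo the centering shift
    A, B, C, D, E, F = coeffs
    mx, my = mean
    D0 = D - 2.0 * A * mx - B * my
    E0 = E - B * mx - 2.0 * C * my
    F0 = F + A * mx * mx + B * mx * my + C * my * my - D * mx - E * my
    return ConicCoefficients(A, B, C, D0, E0, F0)


def conic_to_ellipse(
    c: ConicCoefficients, circularity_threshold: float = CIRCULARITY_THRESHOLD
) -> PupilEllipse:
    """Closed-form conversion of an ellipse conic to geometric parameters.

    The center solves the gradient system; the semi-axes come from the
    eigenvalues of the quadratic form evaluated against the conic's value
    at the center; the minor axis lies along the eigenvector of the
    *larger* eigenvalue.  Near-circular results (a/b below the threshold)
    are flagged degenerate since their orientation is ill-conditioned.
    """
    q = np.array([[c.A, c.B / 2.0], [c.B / 2.0, c.C]])
    center = np.linalg.solve(2.0 * q, [-c.D, -c.E])
    x0, y0 = center
    f_c = (
        c.A * x0 * x0 + c.B * x0 * y0 + c.C * y0 * y0 + c.D * x0 + c.E * y0 + c.F
    )
    eigval, eigvec = np.linalg.eigh(q)
    with np.errstate(invalid="raise"):
        try:
            axes = np.sqrt(-f_c / eigval)
        except FloatingPointError as exc:
            raise ValueError("conic is not a real ellipse") from exc
    # eigh sorts eigenvalues ascending: axes[0] >= axes[1], i.e. the major
    # axis pairs with the smaller eigenvalue, the minor with the larger.
    semi_major, semi_minor = float(axes[0]), float(axes[1])
    minor_dir = eigvec[:, 1]
    angle = float(np.rad2deg(np.arctan2(minor_dir[1], minor_dir[0])) % 180.0)
    degenerate = (
        semi_minor == 0.0 or semi_major / semi_minor < circularity_threshold
    )
    if degenerate:
        angle = angle if not np.isnan(angle) else 0.0
    return PupilEllipse(
        float(x0), float(y0), semi_major, semi_minor, angle, degenerate=degenerate
    )


def fit_ellipse(contour: Contour) -> PupilEllipse:
    """Convenience composition: contour -> conic -> geometric parameters."""
    return conic_to_ellipse(fit_conic(contour))
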