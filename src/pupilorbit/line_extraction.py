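"""Minor-axis extension lines of projected pupils.

Each observed ellipse contributes one straight line: the extension of its
minor axis, which for an ideal projection passes through the ocular
rotational center.  The textbook construction turns the minor-axis angle
into a slope ``G = tan(angle)`` and writes the point-slope equation
``y - yc = G (x - xc)``; that form blows up for a vertical minor axis
(angle 90 degrees), which is a perfectly legitimate gaze direction.  Lines
are therefore represented internally in normal form

    a x + b y = c,   a = sin(theta), b = -cos(theta),

which coincides with the slope form whenever the slope exists and remains
well defined at 90 degrees.  Coefficients are unit-normalized and given a
canonical sign (a > 0, or b > 0 when a = 0) so equal lines have equal
representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CIRCULARITY_THRESHOLD, PupilEllipse

__all__ = ["MinorAxisLine", "gradient_from_rda", "line_from_ppc"]

_VERTICAL_TOL_DEG = 1e-9


@dataclass(frozen=True)
class MinorAxisLine:
    """Normal-form line ``a x + b y = c`` anchored at its ellipse center.

    Invariants: ``a^2 + b^2 = 1``; the anchor lies on the line; the
    canonical sign makes the representation unique per undirected line.
    """

    a: float
    b: float
    c: float
    anchor_x: float
    anchor_y: float
    angle: float

    def __post_init__(self) -> None:
        norm = np.hypot(self.a, self.b)
        if not np.isclose(norm, 1.0, atol=1e-12):
            raise ValueError("line coefficients must satisfy a^2 + b^2 = 1")
        if abs(self.a * self.anchor_x + self.b * self.anchor_y - self.c) > 1e-9:
            raise ValueError("anchor point must lie on the line")

    def signed_distance(self, x: float, y: float) -> float:
        """Perpendicular distance of (x, y) from the line (signed)."""
        return self.a * x + self.b * y - self.c


def gradient_from_rda(rda: float) -> float:
    """Slope of a minor-axis line from its orientation angle, ``tan(rda)``.

    Defined for ``rda`` in [0, 180) away from 90 degrees, where the tangent
    is undefined; vertical lines must go through :func:`line_from_ppc`,
    whose normal form has no singularity.
    """
    if not 0.0 <= rda < 180.0:
        raise ValueError(f"rda must lie in [0, 180), got {rda}")
    if abs(rda - 90.0) <= _VERTICAL_TOL_DEG:
        raise ValueError("vertical line (rda = 90): slope undefined; use line_from_ppc")
    return float(np.tan(np.deg2rad(rda)))


def line_from_ppc(
    e: PupilEllipse, circularity_threshold: float = CIRCULARITY_THRESHOLD
) -> MinorAxisLine:
    """Normal-form equation of an ellipse's minor-axis extension line.

    Raises
    ------
    ValueError
        If the ellipse is direction-degenerate (a circle, or nearly so):
        its minor-axis direction carries no information.
    """
    if e.is_near_circular(circularity_threshold):
        raise ValueError(
            "undefined minor axis: ellipse is direction-degenerate "
            f"(axis ratio {e.axis_ratio:.6g})"
        )
    theta = np.deg2rad(e.minor_axis_angle)
    a = float(np.sin(theta))
    b = float(-np.cos(theta))
    # canonical sign: a > 0, or b > 0 on the vertical-normal boundary
    if a < 0 or (a == 0 and b < 0):
        a, b = -a, -b
    c = a * e.cx + b * e.cy
    return MinorAxisLine(a, b, c, e.cx, e.cy, e.minor_axis_angle)
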