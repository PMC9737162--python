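"""Synthetic pupil-projection datasets for eyeball rotational-center estimation.

The eye is modelled as a pupil of radius ``r`` travelling on a sphere of
radius ``R`` centred on the ocular rotational center point (ORCP).  Under
orthographic projection a circular pupil viewed off-axis appears as an
ellipse: the gaze deviation angle (RAE, rotation angle of the eye) controls
the foreshortening of the minor axis (``b = r cos RAE``) and the offset of
the ellipse center from the ORCP (``d = R sin RAE``), while the gaze
direction angle in the image plane (RDA, rotation direction angle of the
eye) is both the direction of that offset and the orientation of the
projected minor axis.  Consequently every projected pupil's minor-axis
extension line passes through the ORCP — the geometric fact the estimator
in :mod:`pupilorbit.ransac` exploits.

The module generates two kinds of data:

* *ideal* ellipses — exact orthographic projections for random gaze
  directions, all of whose minor-axis lines concur at the ORCP;
* *noise* ellipses — ellipses with uniformly random centers, axes and
  orientations, standing in for spurious pupil detections.

All randomness flows through :class:`numpy.random.Generator` seeded from
the configuration, so identical configurations reproduce bitwise-identical
parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruthModel",
    "GazeAngles",
    "PupilEllipse",
    "DatasetConfig",
    "Contour",
    "project_pupil",
    "generate_ideal_dataset",
    "generate_noise_dataset",
    "ellipse_contour_points",
]

#: a/b ratio below which an ellipse is treated as a circle with no
#: usable minor-axis direction.
CIRCULARITY_THRESHOLD = 1.001


@dataclass(frozen=True)
class GroundTruthModel:
    """Hidden truth of the simulator: pupil orbit model parameters.

    Attributes
    ----------
    orcp_x, orcp_y : float
        Ocular rotational center point, pixels.
    rotation_radius : float
        Radius ``R`` of the sphere on which the pupil center travels, pixels.
    pupil_radius : float
        Physical pupil radius ``r``, pixels; must be smaller than ``R``.
    """

    orcp_x: float
    orcp_y: float
    rotation_radius: float
    pupil_radius: float

    def __post_init__(self) -> None:
        if self.rotation_radius <= 0:
            raise ValueError("rotation_radius must be positive")
        if self.pupil_radius <= 0:
            raise ValueError("pupil_radius must be positive")
        if self.pupil_radius >= self.rotation_radius:
            raise ValueError("pupil_radius must be smaller than rotation_radius")

    @property
    def orcp(self) -> tuple[float, float]:
        return (self.orcp_x, self.orcp_y)


@dataclass(frozen=True)
class GazeAngles:
    """Gaze direction as (RAE, RDA) in degrees.

    ``rae`` in [0, 90] is the deviation of the gaze from the camera axis;
    ``rda`` in [0, 360) is its direction in the image plane, measured
    counter-clockwise from +x.
    """

    rae: float
    rda: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rae <= 90.0:
            raise ValueError(f"rae must lie in [0, 90], got {self.rae}")
        if not 0.0 <= self.rda < 360.0:
            raise ValueError(f"rda must lie in [0, 360), got {self.rda}")


@dataclass(frozen=True)
class PupilEllipse:
    """One projected pupil contour: the method's atomic observation.

    ``minor_axis_angle`` is the orientation of the *minor* axis in degrees,
    normalized to [0, 180) since axis lines are undirected.  For an ideal
    projection it equals the generating RDA modulo 180.  ``degenerate``
    marks ellipses whose minor-axis direction is undefined (circles, i.e.
    frontal gaze); such observations carry no direction information and
    are rejected by line extraction.
    """

    cx: float
    cy: float
    semi_major: float
    semi_minor: float
    minor_axis_angle: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.semi_minor < 0 or self.semi_major < self.semi_minor:
            raise ValueError("require semi_major >= semi_minor >= 0")
        if not 0.0 <= self.minor_axis_angle < 180.0:
            raise ValueError("minor_axis_angle must be normalized to [0, 180)")

    @property
    def center(self) -> tuple[float, float]:
        return (self.cx, self.cy)

    @property
    def axis_ratio(self) -> float:
        """a/b ratio; infinite for a fully foreshortened (segment) ellipse."""
        return np.inf if self.semi_minor == 0 else self.semi_major / self.semi_minor

    def is_near_circular(self, threshold: float = CIRCULARITY_THRESHOLD) -> bool:
        return self.degenerate or self.axis_ratio < threshold


@dataclass(frozen=True)
class DatasetConfig:
    """Configuration of the synthetic experiment's dataset.

    Defaults reproduce the study conditions: a 500x500 px space whose
    center is the true ORCP, 100 ideal projected pupils plus 100 random
    noise ellipses, gaze deviation drawn uniformly between 5 and 85
    degrees (both endpoints of [0, 90] are geometrically singular).
    """

    n_ideal: int = 100
    n_noise: int = 100
    space_width: float = 500.0
    space_height: float = 500.0
    rae_min: float = 5.0
    rae_max: float = 85.0
    noise_axis_min: float = 5.0
    noise_axis_max: float = 60.0
    seed: int = 0
    contour_points_n: int = 64
    contour_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_ideal < 0 or self.n_noise < 0:
            raise ValueError("dataset sizes must be non-negative")
        if self.n_ideal + self.n_noise < 2:
            raise ValueError("need at least two ellipses in total")
        if not 0.0 <= self.rae_min < self.rae_max <= 90.0:
            raise ValueError("require 0 <= rae_min < rae_max <= 90")


@dataclass(frozen=True)
class Contour:
    """Ordered 2-D boundary points of one pupil detection."""

    points: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if pts.shape[0] < 5:
            raise ValueError("a conic fit needs at least 5 contour points")
        object.__setattr__(self, "points", pts)


def project_pupil(model: GroundTruthModel, angles: GazeAngles) -> PupilEllipse:
    """Orthographic projection of the pupil for one gaze direction.

    The ellipse center sits at ``ORCP + R sin(RAE) (cos RDA, sin RDA)``;
    the semi-major axis is the pupil radius and the semi-minor axis is
    foreshortened by ``cos(RAE)``; the minor axis points along the RDA.
    A frontal gaze (RAE = 0) projects to a circle whose minor-axis
    direction is undefined — the returned ellipse is flagged degenerate
    rather than assigned an arbitrary angle.
    """
    rae = np.deg2rad(angles.rae)
    rda = np.deg2rad(angles.rda)
    d = model.rotation_radius * np.sin(rae)
    cx = model.orcp_x + d * np.cos(rda)
    cy = model.orcp_y + d * np.sin(rda)
    a = model.pupil_radius
    b = model.pupil_radius * np.cos(rae)
    if angles.rae == 0.0:
        return PupilEllipse(cx, cy, a, b, 0.0, degenerate=True)
    return PupilEllipse(cx, cy, a, b, angles.rda % 180.0)


def generate_ideal_dataset(
    model: GroundTruthModel, cfg: DatasetConfig
) -> list[PupilEllipse]:
    """Ideal projected pupils for random gaze directions.

    RAE ~ Uniform[rae_min, rae_max], RDA ~ Uniform[0, 360); every
    returned ellipse's minor-axis line passes through the model's ORCP.
    """
    if cfg.n_ideal < 1:
        raise ValueError("n_ideal must be >= 1 for an ideal dataset")
    if cfg.rae_min <= 0.0:
        raise ValueError(
            "rae_min must be > 0: RAE = 0 projects to a circle with no "
            "minor-axis direction"
        )
    rng = np.random.default_rng(cfg.seed)
    rae = rng.uniform(cfg.rae_min, cfg.rae_max, size=cfg.n_ideal)
    rda = rng.uniform(0.0, 360.0, size=cfg.n_ideal)
    return [
        project_pupil(model, GazeAngles(float(t), float(p)))
        for t, p in zip(rae, rda)
    ]


def generate_noise_dataset(cfg: DatasetConfig) -> list[PupilEllipse]:
    """Randomly configured ellipses emulating spurious pupil detections.

    Centers are uniform over the space, orientations uniform over
    [0, 180), and the semi-axes are two independent uniform draws from
    ``[noise_axis_min, noise_axis_max]`` sorted so that a >= b.  A
    distinct stream from the ideal dataset is used so the two can be
    generated independently under one config seed.
    """
    if cfg.n_noise == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    cx = rng.uniform(0.0, cfg.space_width, size=cfg.n_noise)
    cy = rng.uniform(0.0, cfg.space_height, size=cfg.n_noise)
    axes = rng.uniform(cfg.noise_axis_min, cfg.noise_axis_max, size=(cfg.n_noise, 2))
    axes.sort(axis=1)
    angle = rng.uniform(0.0, 180.0, size=cfg.n_noise)
    return [
        PupilEllipse(float(x), float(y), float(a), float(b), float(t))
        for x, y, (b, a), t in zip(cx, cy, axes, angle)
    ]


def ellipse_contour_points(
    e: PupilEllipse, n_points: int, noise_sd: float = 0.0, seed: int = 0
) -> Contour:
    """Sample boundary points of an ellipse, optionally with isotropic noise.

    Points are taken at uniform parametric angles; ``noise_sd`` pixels of
    independent Gaussian noise is added to each coordinate.  Provides the
    contour input consumed by :func:`pupilorbit.ellipse_fit.fit_conic`.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5 (conic fit is underdetermined)")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    theta = np.deg2rad(e.minor_axis_angle)
    u_minor = np.array([np.cos(theta), np.sin(theta)])
    u_major = np.array([-np.sin(theta), np.cos(theta)])
    pts = (
        np.array(e.center)
        + np.outer(e.semi_major * np.cos(t), u_major)
        + np.outer(e.semi_minor * np.sin(t), u_minor)
    )
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return Contour(pts)
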