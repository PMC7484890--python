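"""Linac projection geometry.

Room coordinate frame: the origin is the linac isocenter, X is the lateral
axis, Y the longitudinal axis (gun-target direction), and Z the vertical
axis.  At gantry angle ``theta`` the radiation source sits at

    S(theta) = (SAD * sin(theta), 0, SAD * cos(theta))

so theta = 0 places the source vertically above the isocenter and increasing
theta moves it toward +X.  The beam central axis points from the source
through the isocenter.  Projections are reported on the plane through the
isocenter perpendicular to the beam axis, along the in-plane lateral axis

    u_hat(theta) = (cos(theta), 0, -sin(theta))          (AB direction)

and along +Y (GT direction).  Working at isocenter scale means one detector
pixel subtends ``pixel_iso_mm`` millimetres in this plane; panel-plane
distances are larger by the magnification SDD/SAD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "GeometryError",
    "LinacGeometry",
    "RoomPoint",
    "ProjectionResult",
    "reduce_angle",
    "signed_angle",
    "source_position",
    "project_point",
    "projection_error",
    "error_sweep",
    "iso_mm_to_pixel",
]


class GeometryError(ValueError):
    """Degenerate projection geometry (point at the source, grazing ray, ...)."""


@dataclass(frozen=True)
class LinacGeometry:
    """Static geometry of the linac + flat-panel imager.

    Defaults describe a 1024 x 1024 amorphous-silicon panel at 160 cm from
    the source with a 25.6 cm x 25.6 cm field of view at the isocenter
    (magnification 1.6, hence SAD = 100 cm and 0.25 mm per native pixel at
    isocenter scale).
    """

    sad_cm: float = 100.0
    sdd_cm: float = 160.0
    panel_matrix: int = 1024
    fov_iso_cm: float = 25.6
    integration_time_s: float = 0.433
    angle_step_deg: float = 0.5

    @property
    def pixel_iso_mm(self) -> float:
        """Native pixel pitch at isocenter scale (mm)."""
        return 10.0 * self.fov_iso_cm / self.panel_matrix

    @property
    def magnification(self) -> float:
        return self.sdd_cm / self.sad_cm

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.angle_step_deg))

    @property
    def angle_grid_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angle_step_deg

    @classmethod
    def from_file(cls, path: str | Path) -> "LinacGeometry":
        """Load geometry constants from a YAML or JSON mapping."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass(frozen=True)
class RoomPoint:
    """A point in the treatment-room frame (cm), origin at the isocenter."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise GeometryError("room coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class ProjectionResult:
    """Signed projection of a point onto the isocenter plane.

    ``u_cm`` is the lateral (AB) coordinate along u_hat, ``v_cm`` the
    longitudinal (GT) coordinate along +Y, and ``beta_rad`` the cone angle at
    the source between the central axis and the source->point ray, signed
    positive for gantry angles in the closed interval [-90, 90] degrees.
    """

    u_cm: float
    v_cm: float
    beta_rad: float


def reduce_angle(theta_deg: float) -> float:
    """Reduce any finite angle to [0, 360)."""
    if not math.isfinite(theta_deg):
        raise GeometryError("gantry angle must be finite")
    return float(np.mod(theta_deg, 360.0))


def signed_angle(theta_deg: float) -> float:
    """Reduce an angle to the signed convention (-180, 180]."""
    t = reduce_angle(theta_deg)
    return t if t <= 180.0 else t - 360.0


def source_position(theta_deg: float, geom: LinacGeometry | None = None) -> tuple[float, float]:
    """Radiation-source position (x, z) in cm for gantry angle ``theta_deg``."""
    geom = geom or LinacGeometry()
    th = math.radians(reduce_angle(theta_deg))
    return (geom.sad_cm * math.sin(th), geom.sad_cm * math.cos(th))


def project_point(
    point: RoomPoint, theta_deg: float, geom: LinacGeometry | None = None
) -> ProjectionResult:
    """Project a room point onto the isocenter plane for a gantry angle.

    The ray from the source through the point is intersected with the plane
    through the isocenter perpendicular to the beam axis.  For a point
    (Ox, 0, 0) this reduces to the closed form
    ``u = SAD * Ox * cos(theta) / (SAD - Ox * sin(theta))``.
    """
    geom = geom or LinacGeometry()
    sad = geom.sad_cm
    th = math.radians(reduce_angle(theta_deg))
    sin_t, cos_t = math.sin(th), math.cos(th)
    o = point.as_array()
    src = np.array([sad * sin_t, 0.0, sad * cos_t])
    r = o - src
    r_norm = float(np.linalg.norm(r))
    if r_norm < 1e-12:
        raise GeometryError("point coincides with the radiation source")
    # Distance from the source to the point, measured along the beam axis.
    den = sad - (o[0] * sin_t + o[2] * cos_t)
    if abs(den) < 1e-9:
        raise GeometryError("ray from source to point is parallel to the isocenter plane")
    scale = sad / den
    p = src + scale * r
    u = float(p[0] * cos_t - p[2] * sin_t)
    v = float(p[1])
    cos_beta = float(np.dot(-src, r) / (sad * r_norm))
    beta = math.acos(min(1.0, max(-1.0, cos_beta)))
    # beta is positive on the closed interval [-90, 90] degrees (the +/-90
    # boundaries take the positive branch), negative otherwise.
    if abs(signed_angle(theta_deg)) > 90.0:
        beta = -beta
    return ProjectionResult(u_cm=u, v_cm=v, beta_rad=beta)


def projection_error(
    point: RoomPoint,
    theta_deg: float,
    epsilon_deg: float,
    geom: LinacGeometry | None = None,
) -> float:
    """AB-direction projection position error, in mm at isocenter scale.

    Returns P(theta + epsilon) - P(theta) where epsilon is a gantry-angle
    error in degrees.  Multiply by the magnification SDD/SAD for the error in
    the physical panel plane.
    """
    if not math.isfinite(epsilon_deg):
        raise GeometryError("gantry angle error must be finite")
    geom = geom or LinacGeometry()
    u1 = project_point(point, theta_deg + epsilon_deg, geom).u_cm
    u0 = project_point(point, theta_deg, geom).u_cm
    return 10.0 * (u1 - u0)


def error_sweep(
    point: RoomPoint,
    epsilon_deg: float,
    theta_grid_deg: Sequence[float] | Iterable[float],
    geom: LinacGeometry | None = None,
) -> list[tuple[float, float]]:
    """Per-angle projection errors over a gantry-angle grid.

    Returns ``[(theta, error_mm), ...]``; the sign of the error flips where
    the object's image-displacement direction reverses with gantry rotation.
    """
    grid = list(theta_grid_deg)
    if not grid:
        raise GeometryError("theta grid must be non-empty")
    geom = geom or LinacGeometry()
    return [(float(t), projection_error(point, t, epsilon_deg, geom)) for t in grid]


def iso_mm_to_pixel(
    u_mm: float,
    v_mm: float,
    geom: LinacGeometry | None = None,
    binned: bool = False,
) -> tuple[float, float]:
    """Map isocenter-plane mm coordinates to (column, row) pixel indices.

    (0, 0) mm maps to the image center: (511.5, 511.5) native, (255.5, 255.5)
    binned.  Columns run along the AB axis, rows along GT.
    """
    geom = geom or LinacGeometry()
    half_mm = 10.0 * geom.fov_iso_cm / 2.0
    if abs(u_mm) > half_mm or abs(v_mm) > half_mm:
        raise GeometryError(
            f"point ({u_mm}, {v_mm}) mm falls outside the {geom.fov_iso_cm} cm field of view"
        )
    n = geom.panel_matrix // 2 if binned else geom.panel_matrix
    pitch = geom.pixel_iso_mm * (2.0 if binned else 1.0)
    center = n / 2.0 - 0.5
    return (center + u_mm / pitch, center + v_mm / pitch)


def pixel_to_iso_mm(
    col: float,
    row: float,
    geom: LinacGeometry | None = None,
    binned: bool = False,
) -> tuple[float, float]:
    """Inverse of :func:`iso_mm_to_pixel` (no bounds check)."""
    geom = geom or LinacGeometry()
    n = geom.panel_matrix // 2 if binned else geom.panel_matrix
    pitch = geom.pixel_iso_mm * (2.0 if binned else 1.0)
    center = n / 2.0 - 0.5
    return ((col - center) * pitch, (row - center) * pitch)
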