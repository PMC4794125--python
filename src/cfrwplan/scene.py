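"""Geometric data model for needle-insertion planning.

World frame conventions: the frame Sigma has its origin at needle 1's target,
z vertical-up, units mm, right-handed.  Obstacles (vessels, ribs, inserted
needles) and the two needle parts are all modelled as posed super-quadrics
``sum_i |x_i / a_i|^{e_i} = c`` with even positive exponents, so every implicit
function is smooth (no absolute values are needed) and has closed-form
gradients and Hessians, which the workspace-boundary criterion requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "SuperQuadric",
    "NeedleGeometry",
    "Target",
    "Trajectory",
    "AngleLimits",
    "SkinSurface",
    "EllipticCylinderSkin",
    "PolynomialSkin",
    "SphereSkin",
    "GriddedSkin",
    "Scene",
    "sq_value",
    "sq_gradient",
    "sq_hessian",
    "obstacle_transform",
    "needle_transform",
    "segment_pose",
    "skin_eval",
    "skin_normal",
    "rot_y",
    "rot_z",
]


def rot_y(angle: float) -> np.ndarray:
    """Rotation matrix about the y-axis."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(angle: float) -> np.ndarray:
    """Rotation matrix about the z-axis."""
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion p -> R p + t from a local frame into the world frame."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quat(cls, quat, translation) -> "RigidTransform":
        """Build from a unit quaternion in scalar-last (x, y, z, w) order.

        The quaternion is kept verbatim so serialization round-trips are
        bit-exact (matrix -> quaternion conversion is not).
        """
        q = np.asarray(quat, dtype=float)
        R = Rotation.from_quat(q).as_matrix()
        obj = cls(R, np.asarray(translation, dtype=float))
        object.__setattr__(obj, "_quat", q)
        return obj

    def as_quat(self) -> np.ndarray:
        cached = getattr(self, "_quat", None)
        if cached is not None:
            return cached
        return Rotation.from_matrix(self.rotation).as_quat()

    def apply(self, p: np.ndarray) -> np.ndarray:
        """Map local points (..., 3) into the world frame."""
        p = np.asarray(p)
        return p @ self.rotation.T + self.translation

    def apply_inverse(self, p: np.ndarray) -> np.ndarray:
        p = np.asarray(p)
        return (p - self.translation) @ self.rotation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Composition (self o other)(p) = self(other(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class SuperQuadric:
    """Posed implicit surface sum_i |p'_i / a_i|^{e_i} - c = 0.

    ``p'`` is the point expressed in the local canonical frame.  Exponents must
    be even positive integers (>= 2) so the implicit function is smooth and the
    absolute values drop out; the value at the local origin is exactly ``-c``.
    """

    scales: np.ndarray
    exponents: np.ndarray
    level: float = 1000.0
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    label: str = ""

    def __post_init__(self):
        a = np.asarray(self.scales, dtype=float)
        e = np.asarray(self.exponents)
        if a.shape != (3,) or e.shape != (3,):
            raise ValueError("scales and exponents must be 3-vectors")
        if np.any(a <= 0):
            raise ValueError("scales must be positive")
        e_int = e.astype(int)
        if np.any(e_int != e) or np.any(e_int < 2) or np.any(e_int % 2 != 0):
            raise ValueError("exponents must be even integers >= 2")
        if self.level <= 0:
            raise ValueError("level must be positive")
        object.__setattr__(self, "scales", a)
        object.__setattr__(self, "exponents", e_int)

    # -- local-frame evaluation (supports complex dtype for derivative work) --

    def local_value(self, p_loc):
        p_loc = np.asarray(p_loc)
        return np.sum((p_loc / self.scales) ** self.exponents, axis=-1) - self.level

    def local_gradient(self, p_loc):
        p_loc = np.asarray(p_loc)
        e = self.exponents
        return e * p_loc ** (e - 1) / self.scales**e

    def local_hessian(self, p_loc):
        p_loc = np.asarray(p_loc, dtype=float)
        e = self.exponents
        diag = e * (e - 1) * p_loc ** (e - 2) / self.scales**e
        return np.diag(diag)

    # -- world-frame evaluation through the pose --

    def value(self, p):
        p = np.asarray(p)
        if not np.all(np.isfinite(p)):
            raise ValueError("super-quadric evaluated at a non-finite point")
        return self.local_value(self.pose.apply_inverse(p))

    def gradient(self, p):
        p_loc = self.pose.apply_inverse(np.asarray(p))
        return self.local_gradient(p_loc) @ self.pose.rotation.T

    def hessian(self, p):
        p_loc = self.pose.apply_inverse(np.asarray(p))
        R = self.pose.rotation
        return R @ self.local_hessian(p_loc) @ R.T

    def posed(self, pose: RigidTransform, label: str | None = None) -> "SuperQuadric":
        return replace(self, pose=pose, label=self.label if label is None else label)

    @property
    def half_extents(self) -> np.ndarray:
        """Axis-aligned surface intercepts a_i * c^(1/e_i) in the local frame."""
        return self.scales * self.level ** (1.0 / self.exponents)


def sq_value(sq: SuperQuadric, p) -> float:
    """Implicit value: negative strictly inside, zero on the surface."""
    return sq.value(p)


def sq_gradient(sq: SuperQuadric, p) -> np.ndarray:
    return sq.gradient(p)


def sq_hessian(sq: SuperQuadric, p) -> np.ndarray:
    return sq.hessian(p)


# printed canonical needle-head parameters (axis along local x)
_HEAD_SCALES = (60.0, 0.1, 0.1)
_HEAD_EXPONENTS = (8, 2, 2)
_HEAD_LEVEL = 1000.0


@dataclass(frozen=True)
class NeedleGeometry:
    """Needle split into head and tube, each a canonical (unposed) super-quadric.

    The head's local x-axis is the needle axis; the head solid spans
    ``[-l/2, +l/2]`` along it when ``head_length`` equals the head's axial
    extent.  ``tube_radius`` parameterizes per-trajectory tube obstacles whose
    axial scale depends on the inserted length and is derived at pose time.
    """

    head_length: float
    head_sq: SuperQuadric
    tube_sq: SuperQuadric
    tube_radius: float = 0.9

    def __post_init__(self):
        if self.head_length <= 0:
            raise ValueError("head_length must be positive")
        extent = 2.0 * self.head_sq.half_extents[0]
        if abs(extent - self.head_length) > 1e-6 * max(1.0, extent):
            logger.warning(
                "needle head super-quadric axial extent %.3f mm does not match "
                "head_length %.3f mm", extent, self.head_length,
            )
        if self.head_length > 80.0:
            logger.warning(
                "needle head length %.1f mm is physically implausible for a "
                "coagulation needle; keeping configured value", self.head_length,
            )

    @classmethod
    def default(cls) -> "NeedleGeometry":
        """Printed canonical head; head_length set to the head's axial extent."""
        head = SuperQuadric(_HEAD_SCALES, _HEAD_EXPONENTS, _HEAD_LEVEL, label="needle-head")
        length = 2.0 * head.half_extents[0]
        tube = cls._tube_template(0.9, _HEAD_LEVEL)
        return cls(head_length=length, head_sq=head, tube_sq=tube)

    @classmethod
    def near_line(cls, cross_scale: float = 1e-4) -> "NeedleGeometry":
        """Degenerate-thin needle used by oracle scenes (axis ~ the trajectory)."""
        head = SuperQuadric(
            (60.0, cross_scale, cross_scale), _HEAD_EXPONENTS, _HEAD_LEVEL,
            label="needle-head",
        )
        tube = cls._tube_template(cross_scale * np.sqrt(_HEAD_LEVEL), _HEAD_LEVEL)
        return cls(head_length=2.0 * head.half_extents[0], head_sq=head, tube_sq=tube,
                   tube_radius=cross_scale * float(np.sqrt(_HEAD_LEVEL)))

    @staticmethod
    def _tube_template(radius: float, level: float) -> SuperQuadric:
        # axial scale is a placeholder; tube obstacles are re-scaled per length
        return SuperQuadric(
            (1.0, radius / np.sqrt(level), radius / np.sqrt(level)),
            (8, 2, 2), level, label="needle-tube",
        )

    def tube_for_length(self, length: float) -> SuperQuadric:
        """Tube super-quadric whose axial extent equals ``length``."""
        if length <= 0:
            raise ValueError("tube length must be positive")
        a1 = 0.5 * length / self.tube_sq.level ** (1.0 / self.tube_sq.exponents[0])
        scales = (a1, self.tube_sq.scales[1], self.tube_sq.scales[2])
        return replace(self.tube_sq, scales=np.asarray(scales))


@dataclass(frozen=True)
class Target:
    """Tumor target point with deformation-compensation displacement."""

    position: np.ndarray
    displacement: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "displacement", np.asarray(self.displacement, dtype=float))

    @property
    def compensated(self) -> np.ndarray:
        return self.position + self.displacement

    def displaced(self, delta) -> "Target":
        return Target(self.position, self.displacement + np.asarray(delta, dtype=float))


def direction_angles(direction: np.ndarray) -> tuple[float, float]:
    """Polar angle from +z and full-quadrant azimuth of a direction vector."""
    dx, dy, dz = direction
    rho = float(np.hypot(dx, dy))
    theta = float(np.arctan2(rho, dz))
    phi = float(np.arctan2(dy, dx))
    return theta, phi


@dataclass(frozen=True)
class Trajectory:
    """One needle line: compensated target, skin entry point and angle pair."""

    target: Target
    entry: np.ndarray
    angles: tuple[float, float] = None  # (theta, phi); derived if omitted

    def __post_init__(self):
        entry = np.asarray(self.entry, dtype=float)
        object.__setattr__(self, "entry", entry)
        d = entry - self.target.compensated
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("zero-length trajectory: entry coincides with target")
        theta, phi = direction_angles(d / n)
        if self.angles is None:
            object.__setattr__(self, "angles", (theta, phi))
        else:
            th, ph = self.angles
            dphi = (ph - phi + np.pi) % (2 * np.pi) - np.pi
            if abs(th - theta) > 1e-6 or (abs(dphi) > 1e-6 and theta > 1e-9):
                raise ValueError("angles inconsistent with entry/target geometry")
            object.__setattr__(self, "angles", (float(th), float(ph)))

    @classmethod
    def from_angles(cls, target: Target, theta: float, phi: float,
                    length: float) -> "Trajectory":
        u = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                      np.cos(theta)])
        return cls(target, target.compensated + length * u)

    @property
    def direction(self) -> np.ndarray:
        d = self.entry - self.target.compensated
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.entry - self.target.compensated))

    def point_at_height(self, h: float) -> np.ndarray:
        """Intersection of the needle axis with the plane z = h."""
        d = self.direction
        if abs(d[2]) < 1e-12:
            raise ValueError("trajectory parallel to the z-layers")
        t = (h - self.target.compensated[2]) / d[2]
        return self.target.compensated + t * d

    def crosses_height(self, h: float) -> bool:
        z0 = self.target.compensated[2]
        z1 = self.entry[2]
        return min(z0, z1) - 1e-9 <= h <= max(z0, z1) + 1e-9


@dataclass(frozen=True)
class AngleLimits:
    """Robot/clinical bounds on the polar and azimuthal insertion angles [rad]."""

    theta_min: float = 0.0
    theta_max: float = 1.2
    phi_min: float = -np.pi
    phi_max: float = np.pi

    def __post_init__(self):
        if not (self.theta_min < self.theta_max and self.phi_min < self.phi_max):
            raise ValueError("angle limits must satisfy min < max")

    @property
    def theta_mid(self):
        return 0.5 * (self.theta_max + self.theta_min)

    @property
    def theta_amp(self):
        return 0.5 * (self.theta_max - self.theta_min)

    @property
    def phi_mid(self):
        return 0.5 * (self.phi_max + self.phi_min)

    @property
    def phi_amp(self):
        return 0.5 * (self.phi_max - self.phi_min)

    @property
    def phi_full_circle(self) -> bool:
        return (self.phi_max - self.phi_min) >= 2 * np.pi - 1e-12

    def contains(self, theta: float, phi: float, tol: float = 1e-9) -> bool:
        if not (self.theta_min - tol <= theta <= self.theta_max + tol):
            return False
        if self.phi_full_circle:
            return True
        ph = (phi - self.phi_mid + np.pi) % (2 * np.pi) - np.pi + self.phi_mid
        return self.phi_min - tol <= ph <= self.phi_max + tol


def obstacle_transform(inserted: Trajectory, geom: NeedleGeometry,
                       offset: float | None = None) -> RigidTransform:
    """Pose of an inserted needle's head super-quadric in the world frame.

    Composition: translate to the head center o', then Rz(phi_obs), Ry(theta_obs),
    Ry(pi/2) — so the local x-axis (the canonical head axis) aligns with the
    needle axis.  ``offset`` is the head-center distance from the tip along the
    axis; it defaults to half the head length.
    """
    theta, phi = direction_angles(inserted.direction)
    if offset is None:
        offset = 0.5 * geom.head_length
    u = np.array([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                  np.cos(theta)])
    o = inserted.target.compensated + offset * u
    R = rot_z(phi) @ rot_y(theta) @ rot_y(np.pi / 2)
    return RigidTransform(R, o)


def segment_pose(start: np.ndarray, end: np.ndarray) -> RigidTransform:
    """Pose mapping the local x-axis onto the segment, origin at its midpoint."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    d = end - start
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("degenerate segment")
    theta, phi = direction_angles(d / n)
    R = rot_z(phi) @ rot_y(theta) @ rot_y(np.pi / 2)
    return RigidTransform(R, 0.5 * (start + end))


def needle_transform(q_angles: tuple[float, float], target: Target,
                     geom: NeedleGeometry) -> RigidTransform:
    """Pose of the moving needle's head for angles (theta_j, phi_j).

    Composition: translate to the compensated target, Rz(phi), Ry(theta),
    translate l/2 along the rotated z-axis, then Ry(pi/2).
    """
    theta, phi = q_angles
    T = np.eye(4)
    T[:3, 3] = target.compensated
    Rz4 = np.eye(4)
    Rz4[:3, :3] = rot_z(phi)
    Ry4 = np.eye(4)
    Ry4[:3, :3] = rot_y(theta)
    Tz = np.eye(4)
    Tz[2, 3] = 0.5 * geom.head_length
    Rh = np.eye(4)
    Rh[:3, :3] = rot_y(np.pi / 2)
    M = T @ Rz4 @ Ry4 @ Tz @ Rh
    return RigidTransform(M[:3, :3], M[:3, 3])


# ---------------------------------------------------------------------------
# parametric skin surfaces
# ---------------------------------------------------------------------------


class SkinSurface:
    """Bounded parametric surface S(u, v) of the abdominal epidermis."""

    kind: str = ""
    u_bounds: tuple[float, float]
    v_bounds: tuple[float, float]

    def _check_bounds(self, u, v):
        if not (self.u_bounds[0] - 1e-12 <= u <= self.u_bounds[1] + 1e-12):
            raise ValueError(
                f"parameter u={u} outside bounds {self.u_bounds}")
        if not (self.v_bounds[0] - 1e-12 <= v <= self.v_bounds[1] + 1e-12):
            raise ValueError(
                f"parameter v={v} outside bounds {self.v_bounds}")

    def point(self, u: float, v: float) -> np.ndarray:
        raise NotImplementedError

    def partials(self, u: float, v: float) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def normal(self, u: float, v: float) -> np.ndarray:
        su, sv = self.partials(u, v)
        n = np.cross(su, sv)
        norm = np.linalg.norm(n)
        if norm < 1e-14:
            raise ValueError("degenerate surface normal")
        return n / norm

    def params(self) -> dict:
        raise NotImplementedError


@dataclass
class EllipticCylinderSkin(SkinSurface):
    """Elliptic cylinder about the y-axis: S = c0 + (a sin u, v, b cos u)."""

    semi_x: float
    semi_z: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    u_bounds: tuple[float, float] = (-0.8, 0.8)
    v_bounds: tuple[float, float] = (-80.0, 40.0)
    kind: str = "elliptic_cylinder"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def point(self, u, v):
        self._check_bounds(u, v)
        return self.center + np.array(
            [self.semi_x * np.sin(u), v, self.semi_z * np.cos(u)])

    def partials(self, u, v):
        su = np.array([self.semi_x * np.cos(u), 0.0, -self.semi_z * np.sin(u)])
        sv = np.array([0.0, 1.0, 0.0])
        return su, sv

    def params(self):
        return {"semi_x": self.semi_x, "semi_z": self.semi_z,
                "center": self.center.tolist()}


@dataclass
class PolynomialSkin(SkinSurface):
    """Graph patch S = (u, v, p(u, v)) with polynomial height coefficients.

    ``coeffs`` is a 2D array: z = sum_{i,j} coeffs[i, j] u^i v^j.  A plane
    z = c is the degenerate single-coefficient case.
    """

    coeffs: np.ndarray
    u_bounds: tuple[float, float] = (-100.0, 100.0)
    v_bounds: tuple[float, float] = (-100.0, 100.0)
    kind: str = "polynomial"

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))

    def _z(self, u, v):
        return float(np.polynomial.polynomial.polyval2d(u, v, self.coeffs))

    def point(self, u, v):
        self._check_bounds(u, v)
        return np.array([u, v, self._z(u, v)])

    def partials(self, u, v):
        cu = np.polynomial.polynomial.polyder(self.coeffs, axis=0) \
            if self.coeffs.shape[0] > 1 else np.zeros((1, 1))
        cv = np.polynomial.polynomial.polyder(self.coeffs, axis=1) \
            if self.coeffs.shape[1] > 1 else np.zeros((1, 1))
        zu = float(np.polynomial.polynomial.polyval2d(u, v, np.atleast_2d(cu)))
        zv = float(np.polynomial.polynomial.polyval2d(u, v, np.atleast_2d(cv)))
        return np.array([1.0, 0.0, zu]), np.array([0.0, 1.0, zv])

    def params(self):
        return {"coeffs": self.coeffs.tolist()}


@dataclass
class SphereSkin(SkinSurface):
    """Spherical patch: u = polar angle from +z, v = azimuth, about ``center``."""

    radius: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    u_bounds: tuple[float, float] = (1e-3, np.pi / 2)
    v_bounds: tuple[float, float] = (-np.pi, np.pi)
    kind: str = "sphere"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)

    def point(self, u, v):
        self._check_bounds(u, v)
        return self.center + self.radius * np.array(
            [np.sin(u) * np.cos(v), np.sin(u) * np.sin(v), np.cos(u)])

    def partials(self, u, v):
        r = self.radius
        su = r * np.array([np.cos(u) * np.cos(v), np.cos(u) * np.sin(v), -np.sin(u)])
        sv = r * np.array([-np.sin(u) * np.sin(v), np.sin(u) * np.cos(v), 0.0])
        return su, sv

    def params(self):
        return {"radius": self.radius, "center": self.center.tolist()}


class GriddedSkin(SkinSurface):
    """Spline interpolant of a sampled patch (cubic in each coordinate)."""

    kind = "grid"

    def __init__(self, u_nodes, v_nodes, points):
        from scipy.interpolate import RectBivariateSpline

        self.u_nodes = np.asarray(u_nodes, dtype=float)
        self.v_nodes = np.asarray(v_nodes, dtype=float)
        self.points = np.asarray(points, dtype=float)  # (nu, nv, 3)
        if self.points.shape != (len(self.u_nodes), len(self.v_nodes), 3):
            raise ValueError("points must have shape (len(u), len(v), 3)")
        kx = min(3, len(self.u_nodes) - 1)
        ky = min(3, len(self.v_nodes) - 1)
        self._splines = [
            RectBivariateSpline(self.u_nodes, self.v_nodes, self.points[:, :, k],
                                kx=kx, ky=ky)
            for k in range(3)
        ]
        self.u_bounds = (float(self.u_nodes[0]), float(self.u_nodes[-1]))
        self.v_bounds = (float(self.v_nodes[0]), float(self.v_nodes[-1]))

    @classmethod
    def from_surface(cls, surface: SkinSurface, nu: int = 25, nv: int = 25):
        un = np.linspace(*surface.u_bounds, nu)
        vn = np.linspace(*surface.v_bounds, nv)
        pts = np.array([[surface.point(u, v) for v in vn] for u in un])
        return cls(un, vn, pts)

    def point(self, u, v):
        self._check_bounds(u, v)
        return np.array([float(s.ev(u, v)) for s in self._splines])

    def partials(self, u, v):
        su = np.array([float(s.ev(u, v, dx=1)) for s in self._splines])
        sv = np.array([float(s.ev(u, v, dy=1)) for s in self._splines])
        return su, sv

    def params(self):
        return {"u_nodes": self.u_nodes.tolist(), "v_nodes": self.v_nodes.tolist(),
                "points": self.points.tolist()}


def skin_eval(surface: SkinSurface, u: float, v: float) -> np.ndarray:
    return surface.point(u, v)


def skin_normal(surface: SkinSurface, u: float, v: float) -> np.ndarray:
    surface._check_bounds(u, v)
    return surface.normal(u, v)


@dataclass
class Scene:
    """Full planning scene: anatomy obstacles, skin, targets, needle, limits."""

    obstacles: list
    skin: SkinSurface
    targets: list
    needle: NeedleGeometry
    angle_limits: AngleLimits
    metadata: dict = field(default_factory=dict)
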