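"""Deterministic generators for test and simulation scenes.

The three-target simulation preset is the reference multi-needle planning
environment (three collinear tumor targets, vessel obstacles between liver
and skin, a curved abdominal skin patch); the sphere-obstacle preset is built
for closed-form verification, since a spherical obstacle and a near-line
needle admit an exact tangent-cone description of the workspace boundary.
All generators are pure functions of their arguments: identical inputs give
bit-identical scenes (the RNG seed, where used, is recorded in metadata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .scene import (AngleLimits, EllipticCylinderSkin, NeedleGeometry,
                    RigidTransform, Scene, SphereSkin, SuperQuadric, Target)

__all__ = [
    "ScenePreset",
    "SphereConeOracle",
    "make_three_target_scene",
    "make_sphere_oracle_scene",
    "make_random_vessel_scene",
    "make_single_vessel_scene",
    "PRESETS",
]


@dataclass(frozen=True)
class ScenePreset:
    """Named deterministic generator configuration."""

    name: str
    seed: int = 0
    params: tuple = ()


def _vessel(center, axis, half_length, radius, label,
            level: float = 1000.0) -> SuperQuadric:
    """Elongated vessel super-quadric with its local x-axis along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # rotation taking x-hat onto the axis (stable also for axis ~ -x)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, axis)
    c = float(x @ axis)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else Rotation.from_euler("z", np.pi).as_matrix()
        quat = Rotation.from_matrix(R).as_quat()
    else:
        ang = np.arctan2(np.linalg.norm(v), c)
        quat = Rotation.from_rotvec(ang * v / np.linalg.norm(v)).as_quat()
    pose = RigidTransform.from_quat(quat, np.asarray(center, dtype=float))
    scales = (half_length / level ** (1.0 / 8.0),
              radius / np.sqrt(level), radius / np.sqrt(level))
    return SuperQuadric(scales, (8, 2, 2), level, pose, label=label)


def make_three_target_scene() -> Scene:
    """Three collinear targets with vessel obstacles and a cylindrical skin.

    Targets are at (0,0,0), (0,-15,0), (0,-30,0) mm in the world frame whose
    origin is needle 1's target.  Two primary vessels run between the liver
    and the abdominal wall; the skin is an elliptic-cylinder patch whose top
    spans z ~ 158-185 mm.
    """
    targets = [Target(np.array([0.0, 0.0, 0.0])),
               Target(np.array([0.0, -15.0, 0.0])),
               Target(np.array([0.0, -30.0, 0.0]))]
    vessels = [
        _vessel(center=(12.0, -15.0, 85.0), axis=(0.0, 1.0, 0.0),
                half_length=70.0, radius=4.0, label="vessel-1"),
        _vessel(center=(-22.0, -5.0, 65.0), axis=(1.0, 0.0, 0.0),
                half_length=50.0, radius=5.0, label="vessel-2"),
    ]
    skin = EllipticCylinderSkin(semi_x=170.0, semi_z=185.0,
                                center=np.zeros(3),
                                u_bounds=(-0.55, 0.55),
                                v_bounds=(-80.0, 40.0))
    return Scene(obstacles=vessels, skin=skin, targets=targets,
                 needle=NeedleGeometry.default(),
                 angle_limits=AngleLimits(0.0, 1.0, -np.pi, np.pi),
                 metadata={"preset": "three-target"})


@dataclass(frozen=True)
class SphereConeOracle:
    """Closed-form boundary of a spherical obstacle for a near-line needle.

    A line through the target stays >= gamma from a sphere of radius r whose
    center is D from the target iff its angle from the center direction is at
    least the tangent-cone half-angle arcsin((r + gamma) / D).  In the plane
    z = h the boundary is the circle of radius (h - z_t) tan(half_angle)
    about the axis-piercing point.
    """

    r: float
    D: float
    gamma: float
    target_z: float = 0.0

    @property
    def half_angle(self) -> float:
        return float(np.arcsin((self.r + self.gamma) / self.D))

    def circle_radius(self, h: float) -> float:
        return (h - self.target_z) * float(np.tan(self.half_angle))

    def circle(self, h: float, n: int = 256) -> np.ndarray:
        t = np.linspace(0.0, 2 * np.pi, n, endpoint=True)
        rad = self.circle_radius(h)
        return np.stack([rad * np.cos(t), rad * np.sin(t)], axis=1)


def make_sphere_oracle_scene(r: float = 10.0, D: float = 40.0,
                             gamma: float = 1.5
                             ) -> tuple[Scene, SphereConeOracle]:
    """Single spherical obstacle straight above a single target.

    The needle cross-section is near-degenerate so its axis is effectively
    the trajectory line, making the tangent-cone formula exact up to the
    residual cross-section half-width.
    """
    if D <= r + gamma:
        raise ValueError("target inside the inflated obstacle: need D > r + gamma")
    level = 1000.0
    a = r / np.sqrt(level)
    sphere = SuperQuadric(
        (a, a, a), (2, 2, 2), level,
        RigidTransform.from_quat((0.0, 0.0, 0.0, 1.0), (0.0, 0.0, D)),
        label="sphere")
    skin = SphereSkin(radius=190.0, u_bounds=(1e-3, 1.2),
                      v_bounds=(-np.pi, np.pi))
    scene = Scene(obstacles=[sphere], skin=skin,
                  targets=[Target(np.zeros(3))],
                  needle=NeedleGeometry.near_line(),
                  angle_limits=AngleLimits(0.0, 1.2, -np.pi, np.pi),
                  metadata={"preset": "sphere-oracle", "r": r, "D": D,
                            "gamma": gamma})
    return scene, SphereConeOracle(r=r, D=D, gamma=gamma)


def make_single_vessel_scene() -> Scene:
    """One elongated vessel above one target, near-line needle.

    This is the clearance-verification scene: boundary trajectories traced
    with safe distance gamma should pass the vessel surface at distance
    gamma (up to the barrier bias).
    """
    vessel = _vessel(center=(10.0, 0.0, 90.0), axis=(0.0, 1.0, 0.0),
                     half_length=60.0, radius=4.0, label="vessel")
    skin = EllipticCylinderSkin(semi_x=170.0, semi_z=185.0,
                                center=np.zeros(3),
                                u_bounds=(-0.55, 0.55),
                                v_bounds=(-80.0, 40.0))
    return Scene(obstacles=[vessel], skin=skin, targets=[Target(np.zeros(3))],
                 needle=NeedleGeometry.near_line(),
                 angle_limits=AngleLimits(0.0, 1.0, -np.pi, np.pi),
                 metadata={"preset": "single-vessel"})


def make_random_vessel_scene(seed: int, n_vessels: int = 3,
                             bounds: dict | None = None) -> Scene:
    """Seeded random elongated vessels in the slab between target and skin."""
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    b = {"z": (50.0, 120.0), "xy": (-60.0, 60.0), "radius": (2.0, 6.0),
         "half_length": (30.0, 80.0)}
    if bounds:
        b.update(bounds)
    rng = np.random.default_rng(seed)
    vessels = []
    for k in range(n_vessels):
        center = np.array([rng.uniform(*b["xy"]), rng.uniform(*b["xy"]),
                           rng.uniform(*b["z"])])
        axis = rng.normal(size=3)
        axis[2] *= 0.3  # vessels run mostly horizontally
        axis /= np.linalg.norm(axis)
        vessels.append(_vessel(center, axis,
                               half_length=rng.uniform(*b["half_length"]),
                               radius=rng.uniform(*b["radius"]),
                               label=f"vessel-{k + 1}"))
    skin = EllipticCylinderSkin(semi_x=170.0, semi_z=185.0,
                                center=np.zeros(3),
                                u_bounds=(-0.55, 0.55),
                                v_bounds=(-80.0, 40.0))
    return Scene(obstacles=vessels, skin=skin, targets=[Target(np.zeros(3))],
                 needle=NeedleGeometry.default(),
                 angle_limits=AngleLimits(0.0, 1.0, -np.pi, np.pi),
                 metadata={"preset": "random-vessels", "seed": int(seed),
                           "n_vessels": int(n_vessels)})


PRESETS = {
    "three-target": lambda seed=0: make_three_target_scene(),
    "sphere-oracle": lambda seed=0: make_sphere_oracle_scene()[0],
    "single-vessel": lambda seed=0: make_single_vessel_scene(),
    "random-vessels": lambda seed=0: make_random_vessel_scene(seed),
}
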