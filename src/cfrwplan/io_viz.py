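"""Configuration, scene/plan serialization, boundary export and plotting.

JSON is the canonical config format (bit-exact float round-trips via the
shortest-repr encoding); boundary polylines export to CSV (and optionally
ASCII PLY polylines for 3D viewing); layer plots render the stacked boundary
curves with the planned trajectories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cfrw import CFRWBoundary
from .planner import PlanResult
from .scene import (AngleLimits, EllipticCylinderSkin, GriddedSkin,
                    NeedleGeometry, PolynomialSkin, RigidTransform, Scene,
                    SphereSkin, SuperQuadric, Target)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "scene_to_dict",
    "scene_from_dict",
    "load_scene",
    "save_scene",
    "save_plan",
    "boundaries_to_frame",
    "export_ply",
    "plot_layers",
]


@dataclass
class RunConfig:
    """Planner parameters with validation.

    gamma: safe clearance distance [mm]; mu: interior-point barrier
    parameter; z_layers: heights of the boundary slices [mm]; delta_tol /
    eps_tol: entry-search convergence and step precisions; continuation_step:
    boundary sampling step in the layer plane [mm].
    """

    gamma: float = 1.5
    mu: float = 0.1
    z_layers: tuple = (150.0, 160.0, 170.0)
    delta_tol: float = 1e-5
    eps_tol: float = 1e-4
    continuation_step: float = 0.5
    newton_tol: float = 1e-9
    max_steps: int = 100000
    h_max: float = 200.0
    seed: int = 0
    seed_strategy: str = "project"
    grid_n: int = 8
    truncate_at_skin: bool = True
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("gamma", "mu", "delta_tol", "eps_tol",
                     "continuation_step", "newton_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        self.z_layers = tuple(float(z) for z in self.z_layers)
        for z in self.z_layers:
            if not 0.0 <= z <= self.h_max:
                raise ValueError(
                    f"z_layers entry {z} outside [0, h_max={self.h_max}]")
        if self.seed_strategy not in ("project", "grid"):
            raise ValueError("seed_strategy must be 'project' or 'grid'")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# scene (de)serialization
# ---------------------------------------------------------------------------


def _sq_to_dict(sq: SuperQuadric, with_pose: bool = True) -> dict:
    d = {
        "scales": sq.scales.tolist(),
        "exponents": sq.exponents.tolist(),
        "level": sq.level,
        "label": sq.label,
    }
    if with_pose:
        d["rotation"] = sq.pose.as_quat().tolist()
        d["translation"] = sq.pose.translation.tolist()
    return d


def _sq_from_dict(d: dict, context: str) -> SuperQuadric:
    for key in ("scales", "exponents", "level"):
        if key not in d:
            raise ValueError(f"{context}: missing required field '{key}'")
    pose = RigidTransform.identity()
    if "rotation" in d or "translation" in d:
        pose = RigidTransform.from_quat(
            d.get("rotation", [0.0, 0.0, 0.0, 1.0]),
            d.get("translation", [0.0, 0.0, 0.0]))
    try:
        return SuperQuadric(d["scales"], d["exponents"], d["level"], pose,
                            label=d.get("label", ""))
    except ValueError as exc:
        raise ValueError(f"{context}: {exc}") from exc


_SKIN_KINDS = {"elliptic_cylinder", "polynomial", "sphere", "grid"}


def _skin_to_dict(skin) -> dict:
    return {"kind": skin.kind, "params": skin.params(),
            "u_bounds": list(skin.u_bounds), "v_bounds": list(skin.v_bounds)}


def _skin_from_dict(d: dict):
    kind = d.get("kind")
    if kind not in _SKIN_KINDS:
        raise ValueError(
            f"scene.skin.kind: '{kind}' not one of {sorted(_SKIN_KINDS)}")
    p = d.get("params", {})
    ub = tuple(d["u_bounds"])
    vb = tuple(d["v_bounds"])
    if kind == "elliptic_cylinder":
        return EllipticCylinderSkin(semi_x=p["semi_x"], semi_z=p["semi_z"],
                                    center=np.asarray(p["center"]),
                                    u_bounds=ub, v_bounds=vb)
    if kind == "polynomial":
        return PolynomialSkin(coeffs=np.asarray(p["coeffs"]),
                              u_bounds=ub, v_bounds=vb)
    if kind == "sphere":
        return SphereSkin(radius=p["radius"], center=np.asarray(p["center"]),
                          u_bounds=ub, v_bounds=vb)
    return GriddedSkin(p["u_nodes"], p["v_nodes"], p["points"])


def scene_to_dict(scene: Scene) -> dict:
    return {
        "scene": {
            "obstacles": [_sq_to_dict(o) for o in scene.obstacles],
            "skin": _skin_to_dict(scene.skin),
            "targets": [
                {"position": t.position.tolist(),
                 "displacement": t.displacement.tolist()}
                for t in scene.targets
            ],
            "needle": {
                "head_length": scene.needle.head_length,
                "head_sq": _sq_to_dict(scene.needle.head_sq, with_pose=False),
                "tube_sq": _sq_to_dict(scene.needle.tube_sq, with_pose=False),
                "tube_radius": scene.needle.tube_radius,
            },
            "angle_limits": {
                "theta_min": scene.angle_limits.theta_min,
                "theta_max": scene.angle_limits.theta_max,
                "phi_min": scene.angle_limits.phi_min,
                "phi_max": scene.angle_limits.phi_max,
            },
            "metadata": scene.metadata,
        }
    }


def scene_from_dict(data: dict) -> Scene:
    if "scene" not in data:
        raise ValueError("config: missing top-level 'scene' object")
    s = data["scene"]
    for key in ("obstacles", "skin", "targets", "needle", "angle_limits"):
        if key not in s:
            raise ValueError(f"scene: missing required field '{key}'")
    obstacles = [_sq_from_dict(o, f"scene.obstacles[{i}]")
                 for i, o in enumerate(s["obstacles"])]
    skin = _skin_from_dict(s["skin"])
    targets = [Target(np.asarray(t["position"], dtype=float),
                      np.asarray(t.get("displacement", [0, 0, 0]),
                                 dtype=float))
               for t in s["targets"]]
    nd = s["needle"]
    needle = NeedleGeometry(
        head_length=nd["head_length"],
        head_sq=_sq_from_dict(nd["head_sq"], "scene.needle.head_sq"),
        tube_sq=_sq_from_dict(nd["tube_sq"], "scene.needle.tube_sq"),
        tube_radius=nd.get("tube_radius", 0.9))
    al = s["angle_limits"]
    try:
        limits = AngleLimits(al["theta_min"], al["theta_max"],
                             al["phi_min"], al["phi_max"])
    except ValueError as exc:
        raise ValueError(f"scene.angle_limits: {exc}") from exc
    return Scene(obstacles=obstacles, skin=skin, targets=targets,
                 needle=needle, angle_limits=limits,
                 metadata=s.get("metadata", {}))


def save_scene(scene: Scene, path) -> None:
    Path(path).write_text(
        json.dumps(scene_to_dict(scene), indent=1, sort_keys=True) + "\n")


def load_scene(path) -> Scene:
    return scene_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# plan / boundary output
# ---------------------------------------------------------------------------


def boundaries_to_frame(boundaries: list[CFRWBoundary]) -> pd.DataFrame:
    rows = []
    for bd in boundaries:
        for ls in bd.layers:
            for ci, curve in enumerate(ls.curves):
                for pi, (x, y) in enumerate(np.asarray(curve)):
                    rows.append((bd.needle_id, ls.obstacle_id, ls.h, ci, pi,
                                 x, y))
    return pd.DataFrame(rows, columns=["needle_id", "obstacle_id", "z_mm",
                                       "curve_index", "point_index",
                                       "x_mm", "y_mm"])


def save_plan(result: PlanResult, out_dir, plots: bool = False) -> dict:
    """Write plan.json and boundaries.csv (and optional plots); return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    plan_path = out / "plan.json"
    plan_path.write_text(
        json.dumps(result.to_dict(), indent=1, sort_keys=True) + "\n")
    paths["plan"] = str(plan_path)
    csv_path = out / "boundaries.csv"
    boundaries_to_frame(result.boundaries).to_csv(csv_path, index=False)
    paths["boundaries"] = str(csv_path)
    if plots:
        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        paths["plots"] = [
            plot_layers(bd, result, plot_dir / f"needle{bd.needle_id}.png")
            for bd in result.boundaries
        ]
    return paths


def export_ply(boundaries: list[CFRWBoundary], path) -> str:
    """ASCII PLY polyline export of all layer curves (for 3D viewers)."""
    verts = []
    edges = []
    for bd in boundaries:
        for ls in bd.layers:
            for curve in ls.curves:
                base = len(verts)
                pts = np.asarray(curve)
                verts.extend([(x, y, ls.h) for x, y in pts])
                edges.extend([(base + i, base + i + 1)
                              for i in range(len(pts) - 1)])
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x", "property float y", "property float z",
        f"element edge {len(edges)}",
        "property int vertex1", "property int vertex2",
        "end_header",
    ]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in verts]
    lines += [f"{i} {j}" for i, j in edges]
    Path(path).write_text("\n".join(lines) + "\n")
    return str(path)


def plot_layers(boundary: CFRWBoundary, result: PlanResult | None,
                path) -> str:
    """Plot one needle's stacked layer curves and the planned trajectories."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heights = sorted({ls.h for ls in boundary.layers})
    cmap = plt.get_cmap("viridis")
    fig, ax = plt.subplots(figsize=(6, 6))
    for ls in boundary.layers:
        color = cmap(heights.index(ls.h) / max(len(heights) - 1, 1))
        for curve in ls.curves:
            pts = np.asarray(curve)
            ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1.0,
                    label=f"z={ls.h:g} mm ({ls.obstacle_id})")
    if result is not None:
        for rec in result.records:
            traj = rec.trajectory
            for h in heights:
                if traj.crosses_height(h):
                    u = traj.point_at_height(h)
                    ax.plot(u[0], u[1], "r+", ms=8)
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7, loc="best")
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("y [mm]")
    ax.set_aspect("equal")
    ax.set_title(f"needle {boundary.needle_id} CFRW boundary "
                 f"(gamma={boundary.gamma:g} mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
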