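"""Sequential multiple-needle planning loop.

Needles are planned in a given insertion order.  For each needle: compensate
its target by the accumulated deformation displacement, assemble the obstacle
set (anatomy plus all previously planned needles, posed as head and tube
super-quadrics), compute the CFRW boundary curves, run the entry-point
search, and append the planned trajectory.  A pluggable displacement provider
supplies per-insertion target displacements (the deformation model itself is
external); the default provider returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cfrw import CFRWBoundary, EmptyCFRWError, cfrw_for_needle
from .distances import (point_surface_distance, segment_segment_distance,
                        segment_surface_distance)
from .entry_search import EntryResult, optimal_entry
from .scene import (NeedleGeometry, Scene, SuperQuadric, Target, Trajectory,
                    obstacle_transform, segment_pose)

__all__ = [
    "DisplacementProvider",
    "ZeroDisplacement",
    "NeedlePlanRecord",
    "PlanResult",
    "plan_all",
    "needle_obstacles",
    "point_surface_distance",
    "segment_surface_distance",
    "segment_segment_distance",
]


class DisplacementProvider:
    """Maps (just-inserted needle index, target index) -> displacement [mm]."""

    def __call__(self, inserted_index: int, target_index: int) -> np.ndarray:
        raise NotImplementedError


class ZeroDisplacement(DisplacementProvider):
    def __call__(self, inserted_index: int, target_index: int) -> np.ndarray:
        return np.zeros(3)


@dataclass
class NeedlePlanRecord:
    """Planned trajectory for one needle plus diagnostics."""

    index: int
    trajectory: Trajectory
    entry_result: EntryResult
    clearances_mm: dict
    layer_summary: list

    def to_dict(self) -> dict:
        t = self.trajectory
        return {
            "needle": self.index,
            "target_mm": t.target.position.tolist(),
            "displacement_mm": t.target.displacement.tolist(),
            "entry_mm": t.entry.tolist(),
            "theta_rad": t.angles[0],
            "phi_rad": t.angles[1],
            "d_min_mm": self.entry_result.d_min,
            "uv": list(self.entry_result.uv),
            "iterations": self.entry_result.iterations,
            "termination": self.entry_result.termination,
            "clearances_mm": self.clearances_mm,
            "layers": self.layer_summary,
        }


@dataclass
class PlanResult:
    """Ordered planned trajectories with clearance diagnostics."""

    records: list = field(default_factory=list)
    boundaries: list = field(default_factory=list)
    gamma: float = 1.5
    mu: float = 0.1
    z_layers: tuple = (150.0, 160.0, 170.0)

    @property
    def trajectories(self):
        return [r.trajectory for r in self.records]

    def to_dict(self) -> dict:
        return {
            "gamma_mm": self.gamma,
            "mu": self.mu,
            "z_layers_mm": list(self.z_layers),
            "needles": [r.to_dict() for r in self.records],
        }


def needle_obstacles(traj: Trajectory, geom: NeedleGeometry, index: int,
                     truncate_at_skin: bool = True,
                     h_max: float = 200.0) -> list[SuperQuadric]:
    """Obstacle super-quadrics representing an inserted needle.

    The head is posed with its center at half the head length from the tip;
    a tube part is added for whatever inserted length remains beyond the
    head.  With ``truncate_at_skin`` false the shaft is extended well past
    the entry point as a conservative full-line obstacle.
    """
    parts = []
    head_pose = obstacle_transform(traj, geom)
    parts.append(geom.head_sq.posed(head_pose, label=f"needle{index}-head"))
    end_len = traj.length if truncate_at_skin else traj.length + 2.0 * h_max
    tube_len = end_len - geom.head_length
    if tube_len > 1e-6:
        p0 = traj.target.compensated + geom.head_length * traj.direction
        p1 = traj.target.compensated + end_len * traj.direction
        tube = geom.tube_for_length(tube_len)
        parts.append(tube.posed(segment_pose(p0, p1),
                                label=f"needle{index}-tube"))
    return parts


def plan_all(scene: Scene, config, displacements: DisplacementProvider | None
             = None) -> PlanResult:
    """Plan all needles in order, treating inserted needles as new obstacles."""
    provider = displacements or ZeroDisplacement()
    result = PlanResult(gamma=config.gamma, mu=config.mu,
                        z_layers=tuple(config.z_layers))
    obstacles = list(scene.obstacles)
    n = len(scene.targets)
    acc_delta = [np.zeros(3) for _ in range(n)]
    for j, tgt in enumerate(scene.targets):
        target = tgt.displaced(acc_delta[j])
        boundary = cfrw_for_needle(
            target, scene.needle, obstacles, config.z_layers, config.gamma,
            config.mu, scene.angle_limits, h_max=config.h_max,
            step=config.continuation_step, seed_strategy=config.seed_strategy,
            grid_n=config.grid_n, tol=config.newton_tol, needle_id=j)
        blocked = sorted({ls.obstacle_id for ls in boundary.layers
                          if ls.fully_infeasible})
        if blocked:
            raise EmptyCFRWError(
                f"needle {j}: empty CFRW; blocking obstacles: {blocked}")
        entry = optimal_entry(scene.skin, target, boundary,
                              delta_tol=config.delta_tol,
                              eps_tol=config.eps_tol)
        traj = Trajectory(target, entry.entry)
        clearances = {
            obs.label: segment_surface_distance(
                traj.target.compensated, traj.entry, obs)
            for obs in obstacles
        }
        summary = [
            {"obstacle": ls.obstacle_id, "z_mm": ls.h,
             "n_curves": len(ls.curves),
             "n_points": int(sum(len(c) for c in ls.curves))}
            for ls in boundary.layers
        ]
        result.records.append(NeedlePlanRecord(j, traj, entry, clearances,
                                               summary))
        result.boundaries.append(boundary)
        obstacles.extend(needle_obstacles(
            traj, scene.needle, j, truncate_at_skin=config.truncate_at_skin,
            h_max=config.h_max))
        for k in range(j + 1, n):
            acc_delta[k] = acc_delta[k] + np.asarray(provider(j, k), dtype=float)
    return result
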