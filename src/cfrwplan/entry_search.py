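"""Optimal entry-point selection on the skin surface.

The optimal trajectory is the shortest feasible one: the entry point on the
parametric skin S(u, v) minimizing the distance to the compensated target,
subject to the trajectory lying inside the needle's CFRW.  The search is the
four-quadrant grid-refinement procedure: evaluate the four quadrant centers
around the incumbent at half-interval offsets, keep the best feasible
candidate, halve the intervals, and stop when either the trajectory aligns
with the surface normal (sine of the angle <= delta) or the interval size
drops below eps.  This is deliberately a local search; an optional coarse
multi-start grid is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cfrw import CFRWBoundary, trajectory_in_cfrw
from .scene import SkinSurface, Target, Trajectory

__all__ = ["GridSearchState", "EntryResult", "optimal_entry",
           "EntrySearchError"]


class EntrySearchError(RuntimeError):
    pass


@dataclass
class GridSearchState:
    """One refinement step: incumbent center, intervals and best distance."""

    center: tuple
    intervals: tuple
    best_point: tuple
    d_min: float
    iteration: int


@dataclass
class EntryResult:
    """Planned entry for one needle with search diagnostics."""

    entry: np.ndarray
    uv: tuple
    d_min: float
    angles: tuple
    iterations: int
    termination: str
    history: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "entry_mm": self.entry.tolist(),
            "uv": list(self.uv),
            "d_min_mm": self.d_min,
            "theta_rad": self.angles[0],
            "phi_rad": self.angles[1],
            "iterations": self.iterations,
            "termination": self.termination,
        }


def _feasible(surface, target, boundary, u, v):
    """Distance and membership of the trajectory to S(u, v); None if infeasible."""
    p = surface.point(u, v)
    vec = p - target.compensated
    dist = float(np.linalg.norm(vec))
    if dist < 1e-9:
        return None
    traj = Trajectory(target, p)
    try:
        ok = trajectory_in_cfrw(traj, boundary)
    except ValueError:
        return None
    return dist if ok else None


def optimal_entry(surface: SkinSurface, target: Target,
                  boundary: CFRWBoundary, delta_tol: float = 1e-5,
                  eps_tol: float = 1e-4, max_iter: int = 200,
                  multi_start: int | None = None) -> EntryResult:
    """Grid-refinement search for the shortest feasible entry point.

    ``delta_tol`` is the convergence precision on the sine of the angle
    between the trajectory and the surface normal; ``eps_tol`` is the step
    precision on the parameter intervals.  Either criterion terminates.
    """
    if delta_tol <= 0 or eps_tol <= 0:
        raise ValueError("delta_tol and eps_tol must be positive")
    if multi_start:
        return _multi_start_search(surface, target, boundary, delta_tol,
                                   eps_tol, max_iter, multi_start)
    u_lo, u_hi = surface.u_bounds
    v_lo, v_hi = surface.v_bounds
    center = (0.5 * (u_lo + u_hi), 0.5 * (v_lo + v_hi))
    L1 = 0.5 * (u_hi - u_lo)
    L2 = 0.5 * (v_hi - v_lo)
    return _refine(surface, target, boundary, center, L1, L2, delta_tol,
                   eps_tol, max_iter, first_start=True)


def _refine(surface, target, boundary, center, L1, L2, delta_tol, eps_tol,
            max_iter, first_start):
    u_lo, u_hi = surface.u_bounds
    v_lo, v_hi = surface.v_bounds
    best = None  # (d, u, v)
    d0 = _feasible(surface, target, boundary, *center)
    if d0 is not None:
        best = (d0, center[0], center[1])
    history = []
    termination = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        offsets = [(+0.5 * L1, +0.5 * L2), (-0.5 * L1, +0.5 * L2),
                   (-0.5 * L1, -0.5 * L2), (+0.5 * L1, -0.5 * L2)]
        for du, dv in offsets:
            u = float(np.clip(center[0] + du, u_lo, u_hi))
            v = float(np.clip(center[1] + dv, v_lo, v_hi))
            d = _feasible(surface, target, boundary, u, v)
            if d is None:
                continue
            cand = (d, u, v)
            if best is None or cand[0] < best[0] - 1e-15 or (
                    abs(cand[0] - best[0]) <= 1e-15
                    and (u, v) < (best[1], best[2])):
                best = cand
        if best is None:
            if it == 1 and first_start:
                raise EntrySearchError(
                    "initial point outside CFRW; supply alternative start")
            raise EntrySearchError("no feasible candidate survives")
        history.append(GridSearchState(center, (L1, L2),
                                       (best[1], best[2]), best[0], it))
        # termination: normal alignment or interval size
        p = surface.point(best[1], best[2])
        n = surface.normal(best[1], best[2])
        vec = p - target.compensated
        sin_angle = float(np.linalg.norm(np.cross(vec, n)) /
                          np.linalg.norm(vec))
        if sin_angle <= delta_tol:
            termination = "normal_alignment"
            break
        if max(L1, L2) <= eps_tol:
            termination = "interval_precision"
            break
        center = (best[1], best[2])
        L1 *= 0.5
        L2 *= 0.5
    d, u, v = best
    entry = surface.point(u, v)
    traj = Trajectory(target, entry)
    return EntryResult(entry=entry, uv=(u, v), d_min=d, angles=traj.angles,
                       iterations=it, termination=termination,
                       history=history)


def _multi_start_search(surface, target, boundary, delta_tol, eps_tol,
                        max_iter, m):
    u_lo, u_hi = surface.u_bounds
    v_lo, v_hi = surface.v_bounds
    us = np.linspace(u_lo, u_hi, m + 2)[1:-1]
    vs = np.linspace(v_lo, v_hi, m + 2)[1:-1]
    L1 = 0.5 * (u_hi - u_lo) / m
    L2 = 0.5 * (v_hi - v_lo) / m
    results = []
    for u in us:
        for v in vs:
            try:
                results.append(_refine(surface, target, boundary,
                                       (float(u), float(v)), L1, L2,
                                       delta_tol, eps_tol, max_iter,
                                       first_start=False))
            except EntrySearchError:
                continue
    if not results:
        raise EntrySearchError("no feasible candidate from any start")
    return min(results, key=lambda r: (r.d_min, r.uv))
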