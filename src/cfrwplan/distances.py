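"""Independent clearance computations.

These routines measure distances to super-quadric surfaces by direct
constrained optimization (SLSQP over the surface with multi-start) or, for
the rod- and sphere-shaped bodies used throughout, by closed-form capsule
formulas.  They share no machinery with the KKT/continuation boundary code,
which makes them usable both as planner diagnostics and as independent
verification oracles.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize

from .scene import SuperQuadric

__all__ = [
    "point_surface_distance",
    "segment_surface_distance",
    "segment_segment_distance",
    "capsule_of",
]


def _radial_surface_point(sq: SuperQuadric, p_loc: np.ndarray) -> np.ndarray:
    """Point where the ray from the local origin through p_loc meets f = 0."""
    d = np.asarray(p_loc, dtype=float)
    if np.linalg.norm(d) < 1e-12:
        d = np.array([1.0, 0.0, 0.0])
    d = d / np.linalg.norm(d)

    def g(t):
        return float(sq.local_value(t * d))

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("unbounded super-quadric ray")
    t0 = brentq(g, 0.0, hi, xtol=1e-12)
    return t0 * d


def point_surface_distance(sq: SuperQuadric, p, n_starts: int = 4) -> float:
    """Euclidean distance from a point to the super-quadric surface f = 0."""
    p_loc = sq.pose.apply_inverse(np.asarray(p, dtype=float))
    x_rad = _radial_surface_point(sq, p_loc)
    starts = [x_rad]
    rng_dirs = np.eye(3)
    for k in range(min(n_starts - 1, 3)):
        starts.append(_radial_surface_point(sq, x_rad + 0.3 *
                                            np.linalg.norm(x_rad) *
                                            rng_dirs[k]))
    best = np.inf
    for x0 in starts:
        res = minimize(
            lambda x: float(np.sum((x - p_loc) ** 2)), x0,
            jac=lambda x: 2.0 * (x - p_loc),
            constraints=[{"type": "eq",
                          "fun": lambda x: float(sq.local_value(x)),
                          "jac": lambda x: sq.local_gradient(x)}],
            method="SLSQP", options={"maxiter": 200, "ftol": 1e-14})
        if res.success or res.fun < best**2:
            best = min(best, float(np.sqrt(max(res.fun, 0.0))))
    return best


def segment_surface_distance(p0, p1, sq: SuperQuadric,
                             n_coarse: int = 48) -> float:
    """Minimum distance between a segment and a super-quadric surface.

    Joint SLSQP minimization over the surface point and the segment
    parameter, multi-started from the best coarse samples.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p0_loc = sq.pose.apply_inverse(p0)
    seg = sq.pose.apply_inverse(p1) - p0_loc

    ts = np.linspace(0.0, 1.0, n_coarse)
    coarse = [point_surface_distance(
        sq, sq.pose.apply(p0_loc + t * seg), n_starts=1) for t in ts]
    order = np.argsort(coarse)[:3]

    def objective(y):
        x, t = y[:3], y[3]
        d = p0_loc + t * seg - x
        return float(d @ d)

    def objective_jac(y):
        x, t = y[:3], y[3]
        d = p0_loc + t * seg - x
        return np.concatenate([-2.0 * d, [2.0 * float(d @ seg)]])

    best = float(np.min(coarse))
    for i in order:
        t0 = float(ts[i])
        x0 = _radial_surface_point(sq, p0_loc + t0 * seg)
        y0 = np.concatenate([x0, [t0]])
        res = minimize(
            objective, y0, jac=objective_jac,
            constraints=[{"type": "eq",
                          "fun": lambda y: float(sq.local_value(y[:3])),
                          "jac": lambda y: np.concatenate(
                              [sq.local_gradient(y[:3]), [0.0]])}],
            bounds=[(None, None)] * 3 + [(0.0, 1.0)],
            method="SLSQP", options={"maxiter": 300, "ftol": 1e-16})
        if np.isfinite(res.fun):
            best = min(best, float(np.sqrt(max(res.fun, 0.0))))
    return best


def segment_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D segments (closed-form clamped)."""
    a0, a1, b0, b1 = (np.asarray(x, dtype=float) for x in (a0, a1, b0, b1))
    u = a1 - a0
    v = b1 - b0
    w = a0 - b0
    A, B, C = u @ u, u @ v, v @ v
    D, E = u @ w, v @ w
    den = A * C - B * B
    if den > 1e-14:
        s = np.clip((B * E - C * D) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = (B * s + E) / C if C > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((B * t - D) / A, 0.0, 1.0) if A > 1e-14 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))


def capsule_of(sq: SuperQuadric):
    """Conservative capsule (segment + radius) circumscribing a rod or sphere.

    Returns (end0, end1, radius) for exponent-(8,2,2) rods with a circular
    cross-section and for spheres, or None when the shape has no such
    description.  The capsule contains the super-quadric solid (the rod's
    cross-radius tapers toward the caps), so capsule distances underestimate
    the true clearance — a safe direction for feasibility checks.
    """
    e = tuple(int(x) for x in sq.exponents)
    he = sq.half_extents
    c = sq.pose.translation
    if e == (2, 2, 2) and abs(he[0] - he[1]) < 1e-12 and \
            abs(he[1] - he[2]) < 1e-12:
        return c.copy(), c.copy(), float(he[0])
    if e[1:] == (2, 2) and abs(sq.scales[1] - sq.scales[2]) < 1e-12:
        axis = sq.pose.rotation[:, 0]
        return c - he[0] * axis, c + he[0] * axis, float(he[1])
    return None
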