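"""Collision-free reachable workspace (CFRW) boundaries.

A needle through a fixed target point is parameterized by the intersection
``u = (x, y)`` of its axis with a horizontal plane z = h.  For one obstacle,
the clearance between the needle solid and the obstacle solid is encoded by an
interior-point KKT system for the closest pair of points between the two
super-quadric bodies:

* 6 stationarity rows  d f0/d eta + lam1 d f_n/d eta + lam2 d f_obs/d eta = 0,
  with f0 = ||a - b||^2, eta = [a; b],
* 2 membership rows    f_n(b) + s1 = 0,  f_obs(a) + s2 = 0,
* 2 barrier rows       lam_i s_i = mu,
* 1 clearance row      ||a - b||^2 - gamma^2 - s_d^2 = 0,

11 equations in 11 unknowns.  Stacked on the 2-row kinematic constraint that
ties u to the angle parameters (v1, v2) this gives the 13-equation extended
system Phi~.  The workspace boundary is the fold of Phi~ with respect to its
13 state unknowns z~: there the Jacobian Phi~_z~ is singular, which the
27-equation criterion G~ expresses with a unit null direction xi.  G~ = 0 is a
one-dimensional curve whose u-projection is the boundary polyline; it is
traced by pseudo-arclength continuation.

Derivatives: the residual is holomorphic in its unknowns (even-power
super-quadrics, trig substitutions), so Jacobians are computed by complex-step
differentiation at machine precision; the curvature block of the criterion
Jacobian uses central differences of the complex-step Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy.spatial.distance import cdist

from .scene import (AngleLimits, NeedleGeometry, SuperQuadric, Target,
                    Trajectory)

__all__ = [
    "PlanarNeedleState",
    "KKTState",
    "CriterionState",
    "BoundaryCurve",
    "LayerCurveSet",
    "CFRWBoundary",
    "CFRWSystem",
    "angle_substitution",
    "kinematic_residual",
    "collision_free_residual",
    "extended_residual",
    "criterion_residual",
    "find_boundary_point",
    "trace_boundary",
    "cfrw_for_needle",
    "trajectory_in_cfrw",
    "point_parity",
    "points_parity",
    "InfeasibleStartError",
    "BoundaryNotFoundError",
    "ContinuationStalledError",
    "EmptyCFRWError",
]

_CSTEP = 1e-30  # complex-step size (exact to machine precision)


class InfeasibleStartError(RuntimeError):
    """Raised when a search start point is not inside the CFRW."""


class BoundaryNotFoundError(RuntimeError):
    """Raised when marching finds no fold within the allowed distance."""


class ContinuationStalledError(RuntimeError):
    """Raised when the predictor-corrector step underflows."""


class EmptyCFRWError(RuntimeError):
    """Raised when a needle has no feasible trajectory at all."""


# state vector layout for z~ (13 entries)
_IA = slice(0, 3)      # a: candidate point on the obstacle
_IB = slice(3, 6)      # b: candidate point on the needle
_IL1, _IL2 = 6, 7      # Lagrange multipliers
_IS1, _IS2 = 8, 9      # membership slacks
_ISD = 10              # clearance slack
_IV1, _IV2 = 11, 12    # unconstrained angle parameters


@dataclass(frozen=True)
class PlanarNeedleState:
    """Needle state in one z-layer: axis intersection u, angle params, height."""

    u: np.ndarray
    w: tuple
    h: float

    def __post_init__(self):
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))


@dataclass(frozen=True)
class KKTState:
    """Closest-pair interior-point state (eta, multipliers, slacks)."""

    eta: np.ndarray
    lam: np.ndarray
    slacks: np.ndarray
    s_d: float

    def __post_init__(self):
        object.__setattr__(self, "eta", np.asarray(self.eta, dtype=float))
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))
        object.__setattr__(self, "slacks", np.asarray(self.slacks, dtype=float))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.eta, self.lam, self.slacks, [self.s_d]])


@dataclass(frozen=True)
class CriterionState:
    """A point on the boundary-criterion curve: u, state z~, null direction xi."""

    u: np.ndarray
    z: np.ndarray
    xi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "u", np.asarray(self.u, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "xi", np.asarray(self.xi, dtype=float))

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.u, self.z, self.xi])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "CriterionState":
        x = np.asarray(x, dtype=float)
        return cls(x[:2], x[2:15], x[15:28])


def angle_substitution(w, limits: AngleLimits) -> tuple[float, float]:
    """Map unconstrained (w1, w2) into the closed angle boxes via sines."""
    w1, w2 = w
    theta = limits.theta_mid + limits.theta_amp * np.sin(w1)
    phi = limits.phi_mid + limits.phi_amp * np.sin(w2)
    return theta, phi


def kinematic_residual(state: PlanarNeedleState, target: Target,
                       limits: AngleLimits) -> np.ndarray:
    """Residual of the axis/layer intersection constraint (2 rows)."""
    theta, phi = angle_substitution(state.w, limits)
    if abs(np.cos(theta)) < 1e-9:
        raise ValueError("tan singularity: |theta| at pi/2")
    xt, yt, zt = target.compensated
    r = (state.h - zt) * np.tan(theta)
    return np.array([
        state.u[0] - r * np.cos(phi) - xt,
        state.u[1] - r * np.sin(phi) - yt,
    ])


def collision_free_residual(kkt: KKTState, needle_sq: SuperQuadric,
                            obs_sq: SuperQuadric, gamma: float,
                            mu: float) -> np.ndarray:
    """The 11-row interior-point closest-pair system for two posed bodies."""
    if gamma <= 0 or mu <= 0:
        raise ValueError("gamma and mu must be positive")
    a = kkt.eta[:3]
    b = kkt.eta[3:]
    l1, l2 = kkt.lam
    s1, s2 = kkt.slacks
    d = a - b
    rows = np.empty(11)
    rows[0:3] = 2.0 * d + l2 * obs_sq.gradient(a)
    rows[3:6] = -2.0 * d + l1 * needle_sq.gradient(b)
    rows[6] = needle_sq.value(b) + s1
    rows[7] = obs_sq.value(a) + s2
    rows[8] = l1 * s1 - mu
    rows[9] = l2 * s2 - mu
    rows[10] = float(d @ d) - gamma**2 - kkt.s_d**2
    return rows


class CFRWSystem:
    """Constraint systems for one needle, one obstacle, one z-layer."""

    def __init__(self, target: Target, geom: NeedleGeometry,
                 obstacle: SuperQuadric, limits: AngleLimits, h: float,
                 gamma: float, mu: float, h_max: float = 200.0,
                 phi_center: float | None = None):
        if gamma <= 0 or mu <= 0:
            raise ValueError("gamma and mu must be positive")
        if not (0.0 <= h <= h_max):
            raise ValueError("layer height outside [0, h_max]")
        self.target = target
        self.geom = geom
        self.obstacle = obstacle
        self.limits = limits
        self.h = float(h)
        self.gamma = float(gamma)
        self.mu = float(mu)
        self.h_max = float(h_max)
        self._pt = target.compensated
        self._Ro = obstacle.pose.rotation
        self._to = obstacle.pose.translation
        # effective sine-substitution parameters.  With a full-circle azimuth
        # range the substitution midpoint is re-centered (e.g. on the obstacle
        # shadow) so the fold of the substitution at phi_mid +- pi — a spurious
        # singularity of the criterion — points away from the region of
        # interest.  The admissible angle set is unchanged.
        self._th_mid = limits.theta_mid
        self._th_amp = limits.theta_amp
        if phi_center is not None and limits.phi_full_circle:
            self._ph_mid = float(phi_center)
            self._ph_amp = np.pi
        else:
            self._ph_mid = limits.phi_mid
            self._ph_amp = limits.phi_amp

    def set_phi_center(self, phi: float) -> None:
        """Re-center the azimuth substitution (full-circle limits only)."""
        if not self.limits.phi_full_circle:
            raise ValueError("azimuth recentering requires full-circle limits")
        self._ph_mid = float(phi)
        self._ph_amp = np.pi

    # ------------------------------------------------------------------
    # residuals (holomorphic; z may be (13,) or (13, B), real or complex)
    # ------------------------------------------------------------------

    def phi(self, u, z):
        """Extended residual Phi~: 2 kinematic + 11 collision-free rows."""
        z = np.asarray(z)
        single = z.ndim == 1
        if single:
            z = z[:, None]
        theta = self._th_mid + self._th_amp * np.sin(z[_IV1])
        phi = self._ph_mid + self._ph_amp * np.sin(z[_IV2])
        ct, st = np.cos(theta), np.sin(theta)
        cp, sp = np.cos(phi), np.sin(phi)
        xt, yt, zt = self._pt
        out = np.empty_like(z, shape=(13,) + z.shape[1:])
        r = (self.h - zt) * st / ct
        out[0] = u[0] - r * cp - xt
        out[1] = u[1] - r * sp - yt

        a = z[_IA]
        b = z[_IB]
        l1, l2 = z[_IL1], z[_IL2]
        s1, s2 = z[_IS1], z[_IS2]
        s_d = z[_ISD]

        # obstacle (fixed pose)
        a_loc = np.einsum("ki,k...->i...", self._Ro, a - self._to[:, None])
        osq = self.obstacle
        ea = osq.exponents[:, None]
        aa = osq.scales[:, None]
        f_o = np.sum((a_loc / aa) ** ea, axis=0) - osq.level
        g_o_loc = ea * a_loc ** (ea - 1) / aa**ea
        g_o = np.einsum("ik,k...->i...", self._Ro, g_o_loc)

        # needle head: pose depends on (theta, phi)
        hsq = self.geom.head_sq
        half_l = 0.5 * self.geom.head_length
        tn = np.stack([xt + half_l * st * cp, yt + half_l * st * sp,
                       zt + half_l * ct])
        # R_n = Rz(phi) Ry(theta) Ry(pi/2), written out column-wise
        Rn = np.empty((3, 3) + theta.shape, dtype=z.dtype)
        Rn[0, 0], Rn[0, 1], Rn[0, 2] = -cp * st, -sp, cp * ct
        Rn[1, 0], Rn[1, 1], Rn[1, 2] = -sp * st, cp, sp * ct
        Rn[2, 0], Rn[2, 1], Rn[2, 2] = -ct, np.zeros_like(ct), -st
        db = b - tn
        b_loc = np.einsum("ki...,k...->i...", Rn, db)
        eb = hsq.exponents[:, None]
        ab = hsq.scales[:, None]
        f_n = np.sum((b_loc / ab) ** eb, axis=0) - hsq.level
        g_n_loc = eb * b_loc ** (eb - 1) / ab**eb
        g_n = np.einsum("ik...,k...->i...", Rn, g_n_loc)

        d = a - b
        out[2:5] = 2.0 * d + l2 * g_o
        out[5:8] = -2.0 * d + l1 * g_n
        out[8] = f_n + s1
        out[9] = f_o + s2
        out[10] = l1 * s1 - self.mu
        out[11] = l2 * s2 - self.mu
        out[12] = np.sum(d * d, axis=0) - self.gamma**2 - s_d**2
        return out[:, 0] if single else out

    def phi_jac_z(self, u, z):
        """Jacobian Phi~_z~ (13 x 13) by complex step."""
        z = np.asarray(z, dtype=float)
        Z = z[:, None] + 1j * _CSTEP * np.eye(13)
        return self.phi(u, Z).imag / _CSTEP

    def _phi_jac_batch(self, u, Zs):
        """Jacobians for a batch of states Zs (13, K) -> (K, 13, 13)."""
        K = Zs.shape[1]
        big = np.repeat(Zs, 13, axis=1).astype(complex)
        big += 1j * _CSTEP * np.tile(np.eye(13), K)
        vals = self.phi(u, big).imag / _CSTEP  # (13, 13*K)
        return vals.reshape(13, K, 13).transpose(1, 0, 2)

    # ------------------------------------------------------------------
    # boundary criterion G~ : R^28 -> R^27
    # ------------------------------------------------------------------

    def criterion_full(self, x):
        """Return (G~, Phi~_z~, row scales) at x = [u, z~, xi]."""
        x = np.asarray(x, dtype=float)
        u, z, xi = x[:2], x[2:15], x[15:28]
        phi = self.phi(u, z)
        M = self.phi_jac_z(u, z)
        G = np.concatenate([phi, M.T @ xi, [xi @ xi - 1.0]])
        col_norms = np.linalg.norm(M, axis=0)
        scales = np.concatenate([
            self._phi_row_scales(M),
            np.maximum(1.0, col_norms),
            [1.0],
        ])
        return G, M, scales

    @staticmethod
    def _phi_row_scales(M):
        return np.maximum(1.0, np.linalg.norm(M, axis=1) * 1e-3)

    def criterion(self, x):
        return self.criterion_full(x)[0]

    # ------------------------------------------------------------------
    # active-clearance branch of the criterion (s_d = 0)
    # ------------------------------------------------------------------
    # On the clearance boundary the fold direction is the s_d coordinate
    # (its Jacobian column is -2 s_d, which vanishes), so the criterion
    # curve restricted to that branch is exactly {Phi~ = 0, s_d = 0}: 13
    # equations over the 14 unknowns y = [u, a, b, lambda, s, v1, v2].
    # Tracing this reduced system avoids the criterion's spurious fold
    # sheets (angle-substitution folds) and needs no curvature tensor.

    @staticmethod
    def reduced_embed(y):
        """Map the reduced unknowns y (14,) to (u, z~) with s_d = 0."""
        y = np.asarray(y, dtype=float)
        z = np.empty(13)
        z[0:10] = y[2:12]
        z[_ISD] = 0.0
        z[_IV1] = y[12]
        z[_IV2] = y[13]
        return y[:2], z

    def reduced_residual(self, y):
        u, z = self.reduced_embed(y)
        return self.phi(u, z)

    def reduced_jac(self, y):
        u, z = self.reduced_embed(y)
        M = self.phi_jac_z(u, z)
        J = np.zeros((13, 14))
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        J[:, 2:12] = M[:, 0:10]
        J[:, 12:14] = M[:, 11:13]
        return J, M

    def reduced_scales(self, M):
        return self._phi_row_scales(M)

    def criterion_jac(self, x):
        """Jacobian of G~ (27 x 28); curvature block by central differences."""
        x = np.asarray(x, dtype=float)
        u, z, xi = x[:2], x[2:15], x[15:28]
        M = self.phi_jac_z(u, z)
        steps = 1e-6 * np.maximum(1.0, np.abs(z))
        Zs = np.concatenate(
            [z[:, None] + np.diag(steps), z[:, None] - np.diag(steps)], axis=1)
        Ms = self._phi_jac_batch(u, Zs)  # (26, 13, 13)
        T = np.empty((13, 13))
        for k in range(13):
            T[:, k] = (Ms[k].T @ xi - Ms[13 + k].T @ xi) / (2.0 * steps[k])
        J = np.zeros((27, 28))
        J[0, 0] = 1.0
        J[1, 1] = 1.0
        J[:13, 2:15] = M
        J[13:26, 2:15] = T
        J[13:26, 15:28] = M.T
        J[26, 15:28] = 2.0 * xi
        return J

    # ------------------------------------------------------------------
    # interior solves
    # ------------------------------------------------------------------

    def angles_from_u(self, u) -> tuple[float, float, float, float]:
        """(theta, phi, v1, v2) of the axis through u; raises if unreachable."""
        xt, yt, zt = self._pt
        dz = self.h - zt
        if dz <= 0:
            raise InfeasibleStartError("layer is not above the target")
        rho = float(np.hypot(u[0] - xt, u[1] - yt))
        theta = float(np.arctan2(rho, dz))
        phi = float(np.arctan2(u[1] - yt, u[0] - xt))
        if not self.limits.contains(theta, phi, tol=1e-12):
            raise InfeasibleStartError(
                f"axis angles (theta={theta:.4f}, phi={phi:.4f}) outside limits")
        r1 = np.clip((theta - self._th_mid) / max(self._th_amp, 1e-300), -1, 1)
        ph = (phi - self._ph_mid + np.pi) % (2 * np.pi) - np.pi
        r2 = np.clip(ph / max(self._ph_amp, 1e-300), -1, 1)
        return theta, phi, float(np.arcsin(r1)), float(np.arcsin(r2))

    def _newton_interior(self, u, z, mu_override=None, tol=1e-9, max_iter=40):
        """Damped Newton on the 11 collision-free rows at fixed u (v fixed)."""
        sys_mu = self.mu
        if mu_override is not None:
            self.mu = mu_override
        # the angle parameters are determined by u; sync them so the kinematic
        # rows hold identically and only the 11 collision-free rows are solved
        _th, _ph, v1, v2 = self.angles_from_u(u)
        z[_IV1], z[_IV2] = v1, v2
        try:
            for _ in range(max_iter):
                M = self.phi_jac_z(u, z)
                F = self.phi(u, z)[2:]
                scales = self._interior_scales(M)
                res = np.max(np.abs(F) / scales)
                if not np.isfinite(res) or res > 1e12:
                    raise _NewtonFailure("interior iteration diverged")
                if res < tol:
                    return z
                J = M[2:, 0:11]
                try:
                    step = np.linalg.solve(J, -F)
                except np.linalg.LinAlgError:
                    raise _NewtonFailure("singular interior Jacobian")
                # fraction-to-boundary: keep multipliers and slacks positive
                alpha = 1.0
                for idx in (_IL1, _IL2, _IS1, _IS2):
                    if step[idx] < 0:
                        alpha = min(alpha, -0.95 * z[idx] / step[idx])
                # Newton residuals need not shrink monotonically here; only
                # guard against leaving the region where the residual is finite
                for _bt in range(30):
                    z_try = z.copy()
                    z_try[0:11] += alpha * step
                    F_try = self.phi(u, z_try)[2:]
                    if np.all(np.isfinite(F_try)):
                        z = z_try
                        break
                    alpha *= 0.5
                else:
                    raise _NewtonFailure("step underflow")
            raise _NewtonFailure("max iterations reached")
        finally:
            self.mu = sys_mu

    @staticmethod
    def _interior_scales(M):
        s = np.maximum(1.0, np.linalg.norm(M[2:], axis=1) * 1e-3)
        return s

    def solve_interior(self, u, z0=None, tol=1e-9):
        """Solve Phi~ = 0 at fixed u.  Raises InfeasibleStartError on failure."""
        u = np.asarray(u, dtype=float)
        theta, phi, v1, v2 = self.angles_from_u(u)
        if z0 is not None:
            z = z0.copy()
            z[_IV1], z[_IV2] = v1, v2
            try:
                return self._newton_interior(u, z, tol=tol)
            except _NewtonFailure:
                pass
        z = self._cold_start(u, theta, phi, v1, v2)
        mu_path = np.geomspace(max(10.0, self.mu * 100), self.mu, 6)
        try:
            for m in mu_path[:-1]:
                z = self._newton_interior(u, z, mu_override=float(m), tol=1e-7)
            return self._newton_interior(u, z, tol=tol)
        except _NewtonFailure as exc:
            raise InfeasibleStartError(
                f"no collision-free state at u={u.tolist()}: {exc}") from exc

    def _cold_start(self, u, theta, phi, v1, v2):
        z = np.zeros(13)
        z[_IV1], z[_IV2] = v1, v2
        axis = np.array([np.sin(theta) * np.cos(phi),
                         np.sin(theta) * np.sin(phi), np.cos(theta)])
        oc = self.obstacle.pose.translation
        t_ax = float(np.clip((oc - self._pt) @ axis, 0.5,
                             max(self.geom.head_length - 0.5, 1.0)))
        b0 = self._pt + t_ax * axis
        a0 = 0.999 * oc + 0.001 * b0
        z[_IA], z[_IB] = a0, b0
        mu0 = max(10.0, self.mu * 100)
        resid = self.phi(u, z)  # membership rows give -f at zero slack
        z[_IS1] = max(1e-2, -float(resid[8]))
        z[_IS2] = max(1e-2, -float(resid[9]))
        z[_IL1] = mu0 / z[_IS1]
        z[_IL2] = mu0 / z[_IS2]
        d2 = float(np.sum((a0 - b0) ** 2))
        z[_ISD] = np.sqrt(max(d2 - self.gamma**2, 1e-4))
        return z


class _NewtonFailure(RuntimeError):
    pass


def extended_residual(state: PlanarNeedleState, kkt: KKTState,
                      system: CFRWSystem) -> np.ndarray:
    """13-row residual Phi~ = [kinematic; collision-free] for explicit states."""
    z = np.concatenate([kkt.as_vector(), list(state.w)])
    return system.phi(state.u, z)


def criterion_residual(cstate: CriterionState, system: CFRWSystem) -> np.ndarray:
    """27-row boundary criterion residual G~."""
    return system.criterion(cstate.as_vector())


# ---------------------------------------------------------------------------
# boundary point location and continuation tracing
# ---------------------------------------------------------------------------


def find_boundary_point(system: CFRWSystem, start_u, direction,
                        march_step: float = 2.0, t_max: float = 400.0,
                        bisect_tol: float = 1e-8, tol: float = 1e-9,
                        ) -> CriterionState:
    """March from an interior point until the fold, then polish on G~ = 0.

    The interior system is re-solved at each marched u (warm-started); the
    fold is bracketed where the corrector first fails, refined by bisection,
    and the criterion state is polished by Gauss-Newton with xi initialized
    from the smallest left singular vector of Phi~_z~.
    """
    start_u = np.asarray(start_u, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    z_in = system.solve_interior(start_u)
    t_in = 0.0
    t = march_step
    t_out = None
    while t <= t_max:
        try:
            z_in = system._newton_interior(start_u + t * direction,
                                           z_in.copy(), tol=tol)
            t_in = t
        except (_NewtonFailure, InfeasibleStartError):
            t_out = t
            break
        t += march_step
    if t_out is None:
        raise BoundaryNotFoundError(
            f"no boundary within {t_max} mm of the start point")
    while t_out - t_in > bisect_tol:
        mid = 0.5 * (t_in + t_out)
        try:
            z_in = system._newton_interior(start_u + mid * direction,
                                           z_in.copy(), tol=tol, max_iter=25)
            t_in = mid
        except (_NewtonFailure, InfeasibleStartError):
            t_out = mid
    u_b = start_u + t_in * direction
    M = system.phi_jac_z(u_b, z_in)
    U, _s, _vt = np.linalg.svd(M)
    xi = U[:, -1]
    x = np.concatenate([u_b, z_in, xi])
    x = _polish_criterion(system, x, tol=tol)
    return CriterionState.from_vector(x)


def _polish_criterion(system: CFRWSystem, x, tol=1e-9, max_iter=40):
    for _ in range(max_iter):
        G, _M, scales = system.criterion_full(x)
        if np.max(np.abs(G) / scales) < tol:
            return x
        J = system.criterion_jac(x)
        step, *_ = np.linalg.lstsq(J, -G, rcond=None)
        if np.linalg.norm(step) > 50.0:
            step *= 50.0 / np.linalg.norm(step)
        x = x + step
    G, _M, scales = system.criterion_full(x)
    if np.max(np.abs(G) / scales) < 100 * tol:
        return x
    raise BoundaryNotFoundError("criterion polish did not converge")


@dataclass
class BoundaryCurve:
    """Traced boundary polyline in one z-layer (u samples plus full states)."""

    points: np.ndarray              # (N, 2)
    states: list = field(default_factory=list)
    closed: bool = True
    exit_reasons: tuple = ("closed", "closed")  # (backward end, forward end)


def trace_boundary(system: CFRWSystem, seed: CriterionState,
                   step: float = 0.5, tol: float = 1e-9,
                   max_steps: int = 100000, max_retries: int = 40,
                   store_states: bool = True) -> BoundaryCurve:
    """Pseudo-arclength predictor-corrector along the boundary curve.

    The continuation runs on the active-clearance branch of the criterion
    ({Phi~ = 0, s_d = 0}; see ``CFRWSystem.reduced_jac``), which is the same
    solution curve of G~ = 0 but immune to the substitution's spurious fold
    sheets.  The arc step targets consecutive u-samples ~``step`` apart but
    is capped in the full-state metric (obstacle end caps move mostly in the
    non-u unknowns); a persistent step factor shrinks on corrector failure
    and relaxes on easy success.  Tracing stops when the u-projection
    returns to the seed (closed curve), reaches an angle-limit fold of the
    substitution, or leaves the square |u_i| <= h_max; open curves are
    traced in both directions from the seed and concatenated.
    """
    y0 = np.concatenate([seed.u, seed.z[0:10], seed.z[11:13]])
    mid_orig, amp_orig = system._ph_mid, system._ph_amp
    if system.limits.phi_full_circle:
        # start with the substitution centered on the seed's azimuth so its
        # wrap fold is diametrically away; stored points are canonicalized
        # back to the caller's frame
        phi_seed = float(mid_orig + amp_orig * np.sin(y0[13]))
        system.set_phi_center(phi_seed)
        y0[13] = 0.0
    trace_mid, trace_amp = system._ph_mid, system._ph_amp
    try:
        y0 = _polish_reduced(system, y0, tol=tol)
        fwd, reason_f, closed = _trace_direction(system, y0, +1.0, step, tol,
                                                 max_steps, max_retries,
                                                 canon_mid=mid_orig)
        if closed:
            pts = fwd
            reasons = ("closed", "closed")
        else:
            system._ph_mid, system._ph_amp = trace_mid, trace_amp
            bwd, reason_b, _ = _trace_direction(system, y0, -1.0, step, tol,
                                                max_steps, max_retries,
                                                canon_mid=mid_orig)
            pts = bwd[::-1] + fwd[1:]
            reasons = (reason_b, reason_f)
    finally:
        system._ph_mid, system._ph_amp = mid_orig, amp_orig
    points = np.asarray([y[:2] for y in pts])
    states = []
    if store_states:
        for y in pts:
            u, z = system.reduced_embed(np.asarray(y))
            M = system.phi_jac_z(u, z)
            U, _s, _vt = np.linalg.svd(M)
            states.append(CriterionState(u, z, U[:, -1]))
    return BoundaryCurve(points, states, closed, reasons)


def _canonicalize(y, system, mid0):
    """Re-express v2 w.r.t. the original substitution center ``mid0``."""
    phi_actual = system._ph_mid + system._ph_amp * np.sin(y[13])
    delta = (phi_actual - mid0 + np.pi) % (2 * np.pi) - np.pi
    yc = y.copy()
    yc[13] = float(np.arcsin(np.clip(delta / np.pi, -1.0, 1.0)))
    return yc


def _trace_direction(system, y0, orient, step, tol, max_steps, max_retries,
                     canon_mid=None):
    y = np.asarray(y0, dtype=float).copy()
    mid0 = system._ph_mid if canon_mid is None else canon_mid
    u0 = y[:2].copy()
    pts = [_canonicalize(y, system, mid0)]
    prev_tan = None
    restricted_orient = False
    arc_u = 0.0  # accumulated u-path length; closure must loop in u
    u_dir0 = None
    fac = 1.0
    closed = False
    reason = "max_steps"
    for _k in range(max_steps):
        J, _M = system.reduced_jac(y)
        _u, _s, vt = np.linalg.svd(J)
        tan = vt[-1]
        if prev_tan is not None:
            if restricted_orient:
                # after an azimuth recentering the v2 component changed
                # meaning; orient on the untouched components only
                if tan[0:12] @ prev_tan[0:12] < 0:
                    tan = -tan
                restricted_orient = False
            elif tan @ prev_tan < 0:
                tan = -tan
        else:
            if tan[0] < 0 or (tan[0] == 0 and tan[1] < 0):
                tan = -tan
            tan = orient * tan
        # target ~step of u-motion per sample; the raw-norm cap is loose
        # because badly-scaled unknowns (barrier slacks) can dominate the
        # tangent — curvature control is left to the corrector guard and
        # the adaptive factor
        tu = np.linalg.norm(tan[:2])
        h_base = min(step / max(tu, 0.01), 50.0 * step)
        success = False
        for _r in range(max_retries):
            h_arc = fac * h_base
            if h_arc < 1e-6:
                raise ContinuationStalledError("continuation stalled")
            y_new, iters = _correct_reduced(system, y + h_arc * tan, tan,
                                            tol, h_arc)
            if y_new is not None:
                success = True
                break
            fac *= 0.5
        if not success:
            raise ContinuationStalledError("corrector kept failing")
        if iters <= 3:
            fac = min(1.0, 1.5 * fac)
        du = y_new[:2] - y[:2]
        arc_u += float(np.linalg.norm(du))
        if u_dir0 is None and np.linalg.norm(du) > 1e-9:
            u_dir0 = du / np.linalg.norm(du)
        y = y_new
        prev_tan = tan
        pts.append(_canonicalize(y, system, mid0))
        u = y[:2]
        if abs(y[12]) >= np.pi / 2 - 1e-3:
            reason = "theta_limit"
            break
        if abs(y[13]) >= np.pi / 2 - 1e-3:
            reason = "phi_limit"
            break
        if system.limits.phi_full_circle and abs(y[13]) > 1.2:
            # the azimuth fold of the sine substitution is not a real
            # boundary on a full circle: slide the substitution center so
            # the curve passes through
            phi_now = system._ph_mid + system._ph_amp * np.sin(y[13])
            system.set_phi_center(phi_now)
            y[13] = 0.0
            pts[-1] = _canonicalize(y, system, mid0)
            restricted_orient = True
        if np.max(np.abs(u)) > system.h_max:
            reason = "domain"
            break
        # closure requires returning near the seed *moving the same way*,
        # so the opposite edge of a thin shadow cannot trigger it
        same_way = (u_dir0 is not None and np.linalg.norm(du) > 1e-9
                    and du @ u_dir0 > 0)
        if arc_u > 4.0 * step and same_way and \
                np.linalg.norm(u - u0) <= 1.2 * step:
            pts.append(pts[0].copy())
            closed = True
            reason = "closed"
            break
    else:
        raise ContinuationStalledError("max continuation steps exceeded")
    return pts, reason, closed


def _correct_reduced(system: CFRWSystem, yp, tan, tol, h_arc, max_iter=10):
    """Bordered Newton corrector on the reduced fold system.

    The correction displacement of the geometric unknowns (u, a, b) is
    bounded by the arc step so the iterate cannot silently jump to a
    distant point of the solution curve; the multiplier/slack unknowns are
    left unguarded since their natural magnitudes vary over orders of
    magnitude along the curve.
    """
    y = yp.copy()
    max_disp = max(2.0 * h_arc, 1.0)
    for it in range(max_iter):
        R = system.reduced_residual(y)
        J, M = system.reduced_jac(y)
        scales = system.reduced_scales(M)
        if np.max(np.abs(R) / scales) < tol:
            return y, it
        F = np.concatenate([R, [tan @ (y - yp)]])
        try:
            d = np.linalg.solve(np.vstack([J, tan]), -F)
        except np.linalg.LinAlgError:
            return None, it
        if not np.all(np.isfinite(d)):
            return None, it
        y = y + d
        if np.linalg.norm(y[:8] - yp[:8]) > max_disp:
            return None, it
    return None, max_iter


def _polish_reduced(system: CFRWSystem, y, tol, max_iter=30):
    y = np.asarray(y, dtype=float).copy()
    for _ in range(max_iter):
        R = system.reduced_residual(y)
        J, M = system.reduced_jac(y)
        scales = system.reduced_scales(M)
        if np.max(np.abs(R) / scales) < tol:
            return y
        d, *_ = np.linalg.lstsq(J, -R, rcond=None)
        if np.linalg.norm(d) > 20.0:
            d *= 20.0 / np.linalg.norm(d)
        y = y + d
    raise BoundaryNotFoundError("reduced-system polish did not converge")


# ---------------------------------------------------------------------------
# per-needle CFRW assembly and membership
# ---------------------------------------------------------------------------


@dataclass
class LayerCurveSet:
    """Boundary curves of one obstacle in one z-layer.

    When every curve closes (directly or via a reachability-circle arc) the
    membership test uses ray-casting parity.  A shadow clipped by the domain
    box leaves open curves whose parity is ill-defined; such layers are
    flagged for exact membership via the interior solve (the curves are
    still kept for export and plotting).
    """

    obstacle_id: str
    h: float
    curves: list                   # list of (N, 2) arrays
    closed: list = field(default_factory=list)
    feasible_parity: int = 1       # parity (0/1) that means "inside CFRW"
    fully_infeasible: bool = False
    states: list = field(default_factory=list)
    exact_membership: bool = False
    obstacle: SuperQuadric | None = None


@dataclass
class CFRWBoundary:
    """Per-obstacle, per-layer boundary curves for one needle."""

    needle_id: int
    gamma: float
    mu: float
    target: Target
    limits: AngleLimits
    h_max: float = 200.0
    layers: list = field(default_factory=list)
    geom: NeedleGeometry | None = None

    def layer_sets(self):
        return self.layers


def points_parity(points, curves) -> np.ndarray:
    """Vectorized ray-crossing parity (0/1) of query points w.r.t. curves.

    Open polylines are closed by the segment joining their endpoints so the
    parity stays well defined.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    count = np.zeros(len(points), dtype=int)
    for pts in curves:
        pts = np.asarray(pts)
        if np.linalg.norm(pts[0] - pts[-1]) > 1e-12:
            pts = np.vstack([pts, pts[0]])
        x1, y1 = pts[:-1, 0], pts[:-1, 1]
        x2, y2 = pts[1:, 0], pts[1:, 1]
        px = points[:, 0][:, None]
        py = points[:, 1][:, None]
        cond = (y1 <= py) != (y2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        crossing = cond & (xint > px)
        count += crossing.sum(axis=1)
    return count % 2


_RETRY_ANGLE = np.sqrt(2.0) / 100.0  # small fixed irrational rotation


def point_parity(point, curves) -> int:
    """Scalar parity with a deterministic rotated-ray retry near vertices."""
    point = np.asarray(point, dtype=float)
    for attempt in range(6):
        ang = attempt * _RETRY_ANGLE
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s], [s, c]])
        p = R @ point
        rot_curves = [np.asarray(pts) @ R.T for pts in curves]
        degenerate = any(
            np.any((np.abs(pts[:, 1] - p[1]) < 1e-9) & (pts[:, 0] >= p[0] - 1e-9))
            for pts in rot_curves
        )
        if not degenerate:
            return int(points_parity(p[None, :], rot_curves)[0])
    return int(points_parity(point[None, :], curves)[0])


def _hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def _dedup_curves(curves, tol):
    kept = []
    for c in curves:
        if not any(_hausdorff(c.points, k.points) < tol for k in kept):
            kept.append(c)
    return kept


def _obstacle_projection_seeds(system: CFRWSystem):
    """Project the obstacle's bounding box onto the layer through the target.

    Projected points are clipped into the reachable disk so obstacles passing
    close to the target (whose shadows extend far beyond the angle limits)
    still yield a usable march goal.
    """
    sq = system.obstacle
    he = sq.half_extents
    corners = np.array([[sx * he[0], sy * he[1], sz * he[2]]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    axes = np.vstack([np.diag(he), -np.diag(he)])
    world = sq.pose.apply(np.vstack([corners, axes]))
    pt = system.target.compensated
    dz = world[:, 2] - pt[2]
    ok = dz > 1.0
    if not np.any(ok):
        return None, None
    scale = (system.h - pt[2]) / dz[ok]
    proj = pt[:2] + scale[:, None] * (world[ok, :2] - pt[:2])
    rho_max = (system.h - pt[2]) * np.tan(system.limits.theta_max)
    rel = proj - pt[:2]
    rho = np.linalg.norm(rel, axis=1)
    clip = rho > 0.9 * rho_max
    rel[clip] *= (0.9 * rho_max / rho[clip])[:, None]
    proj = pt[:2] + rel
    centroid = proj.mean(axis=0)
    radius = float(np.max(np.linalg.norm(proj - centroid, axis=1)))
    return centroid, radius


def _close_with_limit_arc(system: CFRWSystem, curve: BoundaryCurve,
                          step: float) -> np.ndarray:
    """Close an open curve that exits through the angle limit.

    The feasible-region boundary continues along the reachability circle
    (theta = theta_max); the closing arc is chosen on the side whose
    midpoint is infeasible, i.e. where the obstacle shadow covers the
    circle.
    """
    pts = curve.points
    if curve.closed or curve.exit_reasons != ("theta_limit", "theta_limit"):
        return pts
    c = system.target.compensated[:2]
    e0 = pts[0] - c
    e1 = pts[-1] - c
    az0 = float(np.arctan2(e0[1], e0[0]))
    az1 = float(np.arctan2(e1[1], e1[0]))
    rho0 = float(np.linalg.norm(e0))
    rho1 = float(np.linalg.norm(e1))
    rho_m = 0.5 * (rho0 + rho1)
    deltas = [(az0 - az1) % (2 * np.pi), (az0 - az1) % (2 * np.pi) - 2 * np.pi]
    chosen = None
    for delta in deltas:
        mid = az1 + 0.5 * delta
        probe = c + 0.985 * rho_m * np.array([np.cos(mid), np.sin(mid)])
        try:
            system.solve_interior(probe)
        except InfeasibleStartError:
            chosen = delta
            break
    if chosen is None:
        return pts  # degenerate; the parity chord closure applies
    n = max(2, int(abs(chosen) * rho_m / step))
    t = np.linspace(0.0, 1.0, n + 1)[1:]
    az = az1 + chosen * t
    rho = rho1 + (rho0 - rho1) * t
    arc = c + np.stack([rho * np.cos(az), rho * np.sin(az)], axis=1)
    return np.vstack([pts, arc])


def _single_obstacle_curves(target, geom, obs, limits, h, gamma, mu, h_max,
                            step, seed_strategy, grid_n,
                            tol) -> LayerCurveSet | None:
    """Trace all boundary curves of one obstacle in one layer.

    Returns a LayerCurveSet (possibly with no curves when the obstacle casts
    no shadow), or one flagged fully_infeasible when no feasible interior
    point exists.
    """
    system = CFRWSystem(target, geom, obs, limits, h, gamma, mu, h_max)
    label = system.obstacle.label or "obstacle"
    curves: list[BoundaryCurve] = []
    march_starts = []
    if seed_strategy == "grid":
        lim = system.limits
        pt = system.target.compensated
        rho_max = (system.h - pt[2]) * np.tan(lim.theta_max)
        g = np.linspace(-rho_max, rho_max, grid_n)
        cand = [pt[:2] + np.array([gx, gy]) for gx in g for gy in g]
        directions = [np.array([0.0, 1.0])] * len(cand)
    else:
        centroid, radius = _obstacle_projection_seeds(system)
        if centroid is None:
            return LayerCurveSet(label, system.h, [], feasible_parity=0)
        pt = system.target.compensated
        # re-center the azimuth substitution on the shadow so its fold
        # plane points away from the curves being traced
        az_c = float(np.arctan2(centroid[1] - pt[1], centroid[0] - pt[0]))
        system = CFRWSystem(target, geom, obs, limits, h, gamma, mu, h_max,
                            phi_center=az_c)
        rho_max = (system.h - pt[2]) * np.tan(system.limits.theta_max)
        cand, directions = [], []
        # candidate starts across the reachable disk, marching at the
        # projected shadow centroid; several azimuths guard against starts
        # that happen to sit inside the shadow themselves
        for frac in (0.85, 0.6, 0.35, 0.12):
            for k in range(10):
                ang = 2 * np.pi * k / 10 + 0.13
                u0 = pt[:2] + frac * rho_max * np.array([np.cos(ang),
                                                         np.sin(ang)])
                d = centroid - u0
                n = np.linalg.norm(d)
                if n < 1e-6:
                    d = np.array([0.0, 1.0])
                    n = 1.0
                cand.append(u0)
                directions.append(d / n)
    any_feasible = False
    missed = 0
    stalled = 0
    for u0, d0 in zip(cand, directions):
        try:
            system.angles_from_u(u0)
        except InfeasibleStartError:
            continue
        try:
            state = find_boundary_point(system, u0, d0,
                                        march_step=max(2.0, step),
                                        t_max=float(np.linalg.norm(
                                            centroid - u0)) + 2.0 * (radius or
                                                                     10.0) + 50.0
                                        if seed_strategy != "grid" else 400.0)
        except InfeasibleStartError:
            continue
        except BoundaryNotFoundError:
            any_feasible = True
            missed += 1
            if seed_strategy != "grid" and missed >= 4:
                break
            continue
        any_feasible = True
        if abs(state.z[_ISD]) > 1e-3:
            # an angle-limit fold, not a clearance boundary (the criterion
            # is singular there too); reachability handles it analytically
            continue
        if any(np.min(np.linalg.norm(c.points - state.u, axis=1)) < 3 * step
               for c in curves):
            continue
        try:
            curve = trace_boundary(system, state, step=step, tol=tol)
        except ContinuationStalledError:
            stalled += 1
            continue
        curve.points = _close_with_limit_arc(system, curve, step)
        curves.append(curve)
        march_starts.append(np.asarray(u0, dtype=float))
        if seed_strategy != "grid":
            effectively_closed = (curve.closed or np.linalg.norm(
                curve.points[0] - curve.points[-1]) <= 3 * step)
            # a closed curve is the whole boundary component; open curves
            # (shadow clipped by the domain) may have siblings — keep
            # marching from other azimuths for a few more seeds
            if effectively_closed or len(curves) >= 4:
                break
    if not curves:
        if stalled:
            raise ContinuationStalledError(
                f"boundary of obstacle '{label}' at z={system.h} found but "
                "could not be traced from any seed")
        if any_feasible:
            return LayerCurveSet(label, system.h, [], feasible_parity=0,
                                 obstacle=system.obstacle)
        return LayerCurveSet(label, system.h, [], fully_infeasible=True,
                             obstacle=system.obstacle)
    curves = _dedup_curves(curves, tol=4 * step)
    pts_list = [c.points for c in curves]
    closed_flags = [
        c.closed or np.linalg.norm(c.points[0] - c.points[-1]) <= 3 * step
        for c in curves
    ]
    parity = int(points_parity(march_starts[0][None, :], pts_list)[0])
    return LayerCurveSet(label, system.h, pts_list,
                         closed=closed_flags,
                         feasible_parity=parity,
                         states=[c.states for c in curves],
                         exact_membership=not all(closed_flags),
                         obstacle=system.obstacle)


def cfrw_for_needle(target: Target, geom: NeedleGeometry, obstacles,
                    z_layers, gamma: float, mu: float, limits: AngleLimits,
                    h_max: float = 200.0, step: float = 0.5,
                    seed_strategy: str = "project", grid_n: int = 8,
                    tol: float = 1e-9, needle_id: int = 0) -> CFRWBoundary:
    """Assemble the per-obstacle, per-layer CFRW boundary curves of a needle."""
    boundary = CFRWBoundary(needle_id=needle_id, gamma=gamma, mu=mu,
                            target=target, limits=limits, h_max=h_max,
                            geom=geom)
    for h in z_layers:
        if not 0.0 <= h <= h_max:
            raise ValueError(f"layer z={h} outside [0, {h_max}]")
        for obs in obstacles:
            layer = _single_obstacle_curves(target, geom, obs, limits, h,
                                            gamma, mu, h_max, step,
                                            seed_strategy, grid_n, tol)
            if layer is not None:
                boundary.layers.append(layer)
    return boundary


def trajectory_in_cfrw(traj: Trajectory, boundary: CFRWBoundary) -> bool:
    """Membership test: inside every per-obstacle region on every crossed layer."""
    theta, phi = traj.angles
    d = traj.direction
    if abs(d[2]) < 1e-12:
        raise ValueError("trajectory parallel to all z-layers")
    if not boundary.limits.contains(theta, phi):
        return False
    tested = 0
    for ls in boundary.layers:
        if not traj.crosses_height(ls.h):
            continue
        tested += 1
        if ls.fully_infeasible:
            return False
        if not ls.curves:
            continue
        u = traj.point_at_height(ls.h)[:2]
        if ls.exact_membership:
            if not _exact_layer_membership(boundary, ls, u):
                return False
        elif point_parity(u, ls.curves) != ls.feasible_parity:
            return False
    if tested == 0 and boundary.layers:
        raise ValueError("trajectory crosses none of the stored layers")
    return True


def _exact_layer_membership(boundary: CFRWBoundary, ls: LayerCurveSet,
                            u) -> bool:
    """Direct clearance membership for layers whose curves stay open.

    The interior-point system characterizes *stationary* closest pairs and
    a cold start can converge to a non-global pair for long crossing rods,
    so open-curve layers fall back on a direct geometric clearance: the
    needle capsule against the obstacle capsule (or the SLSQP surface
    distance for general shapes), thresholded at the safe distance minus
    the barrier bias so the two membership paths agree on the boundary.
    """
    from .distances import capsule_of, segment_segment_distance, \
        segment_surface_distance

    if boundary.geom is None or ls.obstacle is None:
        raise ValueError("exact membership requires the boundary's needle "
                         "geometry and obstacle")
    geom = boundary.geom
    tgt = boundary.target.compensated
    u = np.asarray(u, dtype=float)
    d = np.array([u[0] - tgt[0], u[1] - tgt[1], ls.h - tgt[2]])
    d /= np.linalg.norm(d)
    p1 = tgt + geom.head_length * d
    r_needle = float(max(geom.head_sq.half_extents[1],
                         geom.head_sq.half_extents[2]))
    cap = capsule_of(ls.obstacle)
    if cap is not None:
        e0, e1, r_obs = cap
        clearance = segment_segment_distance(tgt, p1, e0, e1) - r_obs - r_needle
    else:
        clearance = segment_surface_distance(tgt, p1, ls.obstacle) - r_needle
    fat_bodies = 1 + (r_needle > 0.1)
    bias = fat_bodies * boundary.mu / (2.0 * boundary.gamma)
    return clearance >= boundary.gamma - bias
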