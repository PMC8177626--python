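"""Discrete-time forward simulation of the nonlinear eye plant.

The control/sampling tick is ``dt`` (default 10 ms); each tick is integrated
with ``n_substeps`` semi-implicit inner steps (default 10 x 1 ms): the
angular velocity is advanced first from the torque balance (with the inertia
tensor frozen within the substep), then the orientation is advanced with the
*new* velocity using the exact quaternion exponential, and the eye-fixed
geometry is refreshed.  Static friction is handled as a latch: once the eye
sticks (|omega| < eps and |tau_el + tau_dyn| < chi_stat) the velocity is
zeroed and the eye stays stuck until the elastic torque exceeds chi_stat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import kinematics as kin
from .plant import (
    EyeState,
    PlantConfig,
    elastic_potential,
    elastic_torques,
    inertia_world,
    total_tension,
)

__all__ = ["Trajectory", "step", "simulate", "hold_until_settled", "motor_range_grid", "MotorRangeMap"]

_OMEGA_BLOWUP = 1e3  # rad/s


class SimulationUnstableError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Sampled states of a simulation run at the control tick.

    ``t`` has N+1 entries; ``q``, ``r``, ``omega`` are (N+1, .) state samples
    and ``u`` the (N, 3) inputs applied on each tick.
    """

    t: np.ndarray
    q: np.ndarray
    r: np.ndarray
    omega: np.ndarray
    u: np.ndarray
    tau_el: np.ndarray
    final_state: EyeState | None = None

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.t)
        u_full = np.vstack([self.u, self.u[-1:]]) if len(self.u) else np.zeros((n, 3))
        return pd.DataFrame(
            {
                "t": self.t,
                "rx": self.r[:, 0], "ry": self.r[:, 1], "rz": self.r[:, 2],
                "wx": self.omega[:, 0], "wy": self.omega[:, 1], "wz": self.omega[:, 2],
                "u1": u_full[:, 0], "u2": u_full[:, 1], "u3": u_full[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rotmat(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _elastic_torque_fast(q, P_first, via_seg, cfg) -> np.ndarray:
    """Total elastic torque; P_first is the first routing point per muscle."""
    Q = cfg.Q0 @ _rotmat(q).T
    seg1 = P_first - Q
    seg1_len = np.sqrt((seg1 * seg1).sum(axis=1))
    stretch = seg1_len + via_seg - cfg.l0
    coef = cfg.kappa * np.maximum(stretch, 0.0) / seg1_len
    F = coef[:, None] * seg1
    return np.cross(Q, F).sum(axis=0)


def step(state: EyeState, u: np.ndarray, cfg: PlantConfig) -> EyeState:
    """Advance one control tick of ``cfg.dt`` seconds with input ``u`` held.

    Driver geometry and the world-frame inertia tensor are refreshed once per
    tick (the inertia varies slowly on the 10 ms scale); the torque balance
    and kinematics are integrated on the inner substep grid.
    """
    from .plant import driver_insertions  # local alias, hot path

    new = state.copy()
    new.u = np.asarray(u, dtype=float).copy()
    h = cfg.dt / cfg.n_substeps
    P = driver_insertions(new.u, cfg)
    # first routing point and the fixed remainder of each tendon path
    P_first = np.where(cfg.has_via[:, None], cfg.VIA, P)
    via_seg = np.where(
        cfg.has_via, np.sqrt(((P - cfg.VIA) ** 2).sum(axis=1)), 0.0
    )
    I = inertia_world(new.q, cfg)
    I_inv = np.linalg.inv(I)
    q = new.q
    omega = new.omega.copy()
    stuck = new.stuck
    chi_dyn, chi_stat, eps = cfg.chi_dyn, cfg.chi_stat, cfg.eps_stiction
    for _ in range(cfg.n_substeps):
        tau_el = _elastic_torque_fast(q, P_first, via_seg, cfg)
        if stuck:
            if (tau_el @ tau_el) < chi_stat * chi_stat:
                omega[:] = 0.0
                continue
            stuck = False
        alpha = I_inv @ (tau_el - chi_dyn * omega)
        omega = omega + h * alpha
        sp2 = omega @ omega
        if sp2 > _OMEGA_BLOWUP * _OMEGA_BLOWUP:
            raise SimulationUnstableError(
                f"|omega| = {np.sqrt(sp2):.1f} rad/s exceeds {_OMEGA_BLOWUP}; "
                f"unstable integration for u = {new.u}, dt = {cfg.dt}, "
                f"n_substeps = {cfg.n_substeps}"
            )
        if sp2 < eps * eps:
            tc = tau_el - chi_dyn * omega
            if (tc @ tc) < chi_stat * chi_stat:
                stuck = True
                omega[:] = 0.0
                continue
        # exact exponential update, q(t+h) = exp(omega h / 2) * q
        speed = np.sqrt(sp2)
        half = 0.5 * speed * h
        c, s = np.cos(half), np.sin(half) / speed
        w0, wx, wy, wz = c, s * omega[0], s * omega[1], s * omega[2]
        q0, q1, q2, q3 = q
        q = np.array(
            [
                w0 * q0 - wx * q1 - wy * q2 - wz * q3,
                w0 * q1 + wx * q0 + wy * q3 - wz * q2,
                w0 * q2 - wx * q3 + wy * q0 + wz * q1,
                w0 * q3 + wx * q2 - wy * q1 + wz * q0,
            ]
        )
        q /= np.sqrt(q @ q)
    if q[0] < 0:
        q = -q
    new.q = q
    new.omega = omega
    new.stuck = stuck
    return new


def simulate(U: np.ndarray, x0: EyeState, cfg: PlantConfig) -> Trajectory:
    """Run the plant for the input series ``U`` (N x 3, one row per tick)."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.size == 0:
        U = np.zeros((0, 3))
    n = len(U)
    t = cfg.dt * np.arange(n + 1)
    q = np.empty((n + 1, 4))
    r = np.empty((n + 1, 3))
    omega = np.empty((n + 1, 3))
    tau = np.empty((n + 1, 3))
    state = x0.copy()
    for i in range(n + 1):
        q[i] = state.q
        r[i] = kin.quat_to_rotvec(state.q)
        omega[i] = state.omega
        _, tau[i] = elastic_torques(state, cfg)
        if i < n:
            state = step(state, U[i], cfg)
    return Trajectory(
        t=t, q=q, r=r, omega=omega, u=U.copy(), tau_el=tau, final_state=state
    )


def hold_until_settled(
    state: EyeState,
    u: np.ndarray,
    cfg: PlantConfig,
    *,
    omega_tol_deg_s: float = 0.5,
    hold_s: float = 0.1,
    timeout_s: float = 5.0,
) -> tuple[EyeState, bool]:
    """Hold ``u`` constant until |omega| stays below tolerance for ``hold_s``."""
    tol = np.radians(omega_tol_deg_s)
    need = max(1, int(round(hold_s / cfg.dt)))
    state = state.copy()
    quiet = 0
    for _ in range(int(round(timeout_s / cfg.dt))):
        state = step(state, u, cfg)
        quiet = quiet + 1 if np.linalg.norm(state.omega) < tol else 0
        if quiet >= need:
            return state, True
    return state, False


# --- static motor-range map --------------------------------------------------


@dataclass
class MotorRangeMap:
    """Settled orientations over a grid of motor commands."""

    u: np.ndarray          # (n, 3) motor commands (rad)
    r: np.ndarray          # (n, 3) settled rotation vectors (half-radians)
    tension: np.ndarray    # (n,) total static tendon tension (N)
    settled: np.ndarray    # (n,) bool


def _static_equilibrium(u: np.ndarray, cfg: PlantConfig, r_init: np.ndarray) -> np.ndarray:
    """Orientation minimizing the elastic potential at fixed u.

    Equilibria of the torque balance are stationary points of the elastic
    potential, so a quasi-Newton descent in rotation-vector coordinates finds
    the settled orientation without time-stepping (stiction leaves the true
    plant anywhere inside a narrow band around this point).
    """

    def fun(r):
        return elastic_potential(kin.rotvec_to_quat(r), u, cfg)

    res = minimize(fun, r_init, method="BFGS", options={"gtol": 1e-10, "maxiter": 200})
    return res.x


def motor_range_grid(
    cfg: PlantConfig,
    n_per_axis: int = 21,
    u_range_deg: float = 35.0,
    *,
    method: str = "static",
) -> MotorRangeMap:
    """Settled eye orientations for an n^3 grid of motor combinations.

    ``method='static'`` minimizes the elastic potential (fast, ignores the
    stiction band); ``method='simulate'`` holds each command through the
    forward simulation until the settling criterion is met.
    """
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    vals = (
        np.array([0.0])
        if n_per_axis == 1
        else np.radians(np.linspace(-u_range_deg, u_range_deg, n_per_axis))
    )
    grid = np.array(np.meshgrid(vals, vals, vals, indexing="ij")).reshape(3, -1).T
    r_out = np.zeros_like(grid)
    tension = np.zeros(len(grid))
    settled = np.ones(len(grid), dtype=bool)
    if method == "static":
        r_prev = np.zeros(3)
        for i, u in enumerate(grid):
            # warm start from the previous solution along the scan order
            r_eq = _static_equilibrium(u, cfg, r_prev)
            r_out[i] = r_eq
            tension[i] = total_tension(kin.rotvec_to_quat(r_eq), u, cfg)
            r_prev = r_eq
    elif method == "simulate":
        for i, u in enumerate(grid):
            st, ok = hold_until_settled(EyeState(), u, cfg)
            r_out[i] = kin.quat_to_rotvec(st.q)
            tension[i] = total_tension(st.q, u, cfg)
            settled[i] = ok
    else:
        raise ValueError(f"unknown method {method!r}")
    return MotorRangeMap(u=grid, r=r_out, tension=tension, settled=settled)
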