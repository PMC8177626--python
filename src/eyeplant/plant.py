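"""Mechanical model of a tendon-driven 3D eye plant.

Six elastic tendons (the analogues of MR, LR, SR, IR, SO, IO) pull on a rigid
globe from insertion points ``Q_i`` (eye-fixed).  Four of them (SR, IR, SO,
IO) are routed through fixed craniocentric via points ``X_i`` ("pulleys");
the horizontal recti (MR, LR) run directly to their cranial end-insertions
``P_i``.  Three motorized drivers rotate rigid rods whose two ends carry the
cranial insertions of an antagonistic muscle pair, so that one tendon of the
pair lengthens while the other slackens:

* driver 1 (u1) — vertical recti SR/IR (rod length L_M = 20 cm);
* driver 2 (u2) — horizontal recti MR/LR (rod length L_R = 28 cm);
* driver 3 (u3) — obliques SO/IO (rod length L_M = 20 cm).

Forces follow Hooke's law with a common tendon elasticity (6.0 N/m), clamped
to zero when a tendon goes slack; torques are moment arms Q_i x F_i.  The
globe feels viscous drag (chi_dyn) and a small static friction (chi_stat)
that cancels sub-threshold torques at near-zero angular velocity.  The
inertia tensor is orientation dependent, I(R) = R I0 R^T.

All geometry is stored internally in SI units (meters); the YAML serialization
uses centimeters, mirroring the reference prototype's coordinate table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .kinematics import qidentity, rotmat_from_quat

__all__ = [
    "MuscleSpec",
    "PlantConfig",
    "EyeState",
    "driver_insertions",
    "eye_insertions",
    "muscle_lengths",
    "muscle_forces",
    "elastic_torques",
    "friction_torque",
    "inertia_world",
    "angular_acceleration",
    "gyroscopic_ratio",
    "elastic_potential",
    "total_tension",
    "load_plant",
    "save_plant",
]

MUSCLE_NAMES = ("MR", "LR", "SR", "IR", "SO", "IO")

# Rest-pose coordinate table, centimeters, eye-centered head-fixed frame.
# Columns: Q0 (globe insertion), X (via point, None for the horizontal recti),
# P0 (cranial insertion at rest).
_TABLE1_CM = {
    "MR": {"q0": (-0.7, 7.5, 0.0), "via": None, "p0": (-32.3, 14.0, 0.5)},
    "LR": {"q0": (-0.7, -7.5, 0.0), "via": None, "p0": (-32.3, -14.0, 0.5)},
    "SR": {"q0": (-0.7, 0.53, 5.3), "via": (-20.6, -7.5, -5.3), "p0": (-43.6, -8.4, -7.9)},
    "IR": {"q0": (-0.7, 0.53, -5.3), "via": (-20.6, -7.5, 5.3), "p0": (-43.6, -8.4, 12.1)},
    "SO": {"q0": (-0.7, -0.53, 5.3), "via": (-15.0, 15.0, 6.3), "p0": (-43.6, 8.4, 12.1)},
    "IO": {"q0": (-0.7, -0.53, -5.3), "via": (-15.0, 15.0, -6.3), "p0": (-43.6, 8.4, -7.9)},
}

# Driver assignment and rod-end kinematic signs.  Each driver rotates a rigid
# rod; the rod ends move by +/- (L/2) sin(u) along x (opposite signs for the
# two ends) and toward the pivot plane by (L/2)(1 - cos u) along the rod axis
# (y for the horizontal recti, z for the others).  ``sin_sign`` is chosen so
# that positive driver angles stretch the muscle producing a positive
# rotation-vector component (u1 -> +ry, u2 -> +rz, u3 -> +rx); ``cos_sign``
# follows from which rod end the muscle occupies.
_DRIVER_TABLE = {
    "MR": {"driver": 2, "sin_sign": -1.0, "cos_sign": -1.0, "cos_axis": 1},
    "LR": {"driver": 2, "sin_sign": +1.0, "cos_sign": +1.0, "cos_axis": 1},
    "SR": {"driver": 1, "sin_sign": +1.0, "cos_sign": +1.0, "cos_axis": 2},
    "IR": {"driver": 1, "sin_sign": -1.0, "cos_sign": -1.0, "cos_axis": 2},
    "SO": {"driver": 3, "sin_sign": +1.0, "cos_sign": -1.0, "cos_axis": 2},
    "IO": {"driver": 3, "sin_sign": -1.0, "cos_sign": +1.0, "cos_axis": 2},
}

# Inertia tensor of the prototype globe, kg m^2.
_I0 = 1e-4 * np.array(
    [
        [4.759, -0.010, 0.111],
        [-0.010, 4.316, 0.0],
        [0.111, 0.0, 3.956],
    ]
)


@dataclass
class MuscleSpec:
    """One tendon: geometry (meters), elasticity and driver coupling."""

    name: str
    q0: np.ndarray          # insertion on the globe at rest (m)
    via: np.ndarray | None  # craniocentric via point (m); None for MR/LR
    p0: np.ndarray          # cranial end-insertion at rest (m)
    kappa: float = 6.0      # tendon elasticity (N/m)
    driver: int = 1         # driver index in {1, 2, 3}
    sin_sign: float = 1.0
    cos_sign: float = 1.0
    cos_axis: int = 2       # coordinate moved by the (1-cos) term: 1=y, 2=z
    rod_length: float = 0.20
    l0: float = 0.0         # rest (slack) length (m); set by PlantConfig


@dataclass
class EyeState:
    """Orientation, angular velocity, motor command and stiction latch."""

    q: np.ndarray = field(default_factory=qidentity)
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))
    u: np.ndarray = field(default_factory=lambda: np.zeros(3))
    stuck: bool = False

    def copy(self) -> "EyeState":
        return EyeState(self.q.copy(), self.omega.copy(), self.u.copy(), self.stuck)


class PlantConfig:
    """Full mechanical description of the eye plant.

    Parameters
    ----------
    muscles : list of MuscleSpec, in canonical order (MR, LR, SR, IR, SO, IO)
    lm, lr_rod : driver rod lengths in meters (vertical/oblique and lateral)
    chi_dyn : dynamic (viscous) friction coefficient, N m s/rad
    chi_stat : static friction threshold, N m
    eps_stiction : velocity cutoff below which static friction can engage, rad/s
    inertia : 3x3 inertia tensor in the primary frame, kg m^2
    dz_cm : common vertical (spatial z) shift of the cranial insertions, cm
    shift_via_points : whether the via points co-move with a dz_cm shift
    pretension : fraction by which rest lengths undercut the rest-pose path
        lengths, l0 = (1 - pretension) * l(rest); keeps all tendons taut
    dt : control/sampling tick (s)
    n_substeps : inner integration substeps per tick
    """

    def __init__(
        self,
        muscles: list[MuscleSpec],
        *,
        lm: float = 0.20,
        lr_rod: float = 0.28,
        chi_dyn: float = 0.02,
        chi_stat: float = 0.006,
        eps_stiction: float = 0.01,
        inertia: np.ndarray | None = None,
        dz_cm: float = 0.0,
        shift_via_points: bool = True,
        pretension: float = 0.05,
        dt: float = 0.01,
        n_substeps: int = 10,
        eye_radius: float = 0.07,
    ) -> None:
        self.muscles = muscles
        self.lm = lm
        self.lr_rod = lr_rod
        self.chi_dyn = chi_dyn
        self.chi_stat = chi_stat
        self.eps_stiction = eps_stiction
        self.inertia = _I0.copy() if inertia is None else np.asarray(inertia, float)
        self.dz_cm = dz_cm
        self.shift_via_points = shift_via_points
        self.pretension = pretension
        self.dt = dt
        self.n_substeps = n_substeps
        self.eye_radius = eye_radius
        self._base_muscles = copy.deepcopy(muscles)  # pre-shift geometry
        self._apply_dz()
        self._compile()
        self._set_rest_lengths()

    # -- construction ---------------------------------------------------------

    @classmethod
    def table1(cls, **kwargs) -> "PlantConfig":
        """The default plant: the reference prototype's coordinate table."""
        muscles = []
        for name in MUSCLE_NAMES:
            geom = _TABLE1_CM[name]
            drv = _DRIVER_TABLE[name]
            muscles.append(
                MuscleSpec(
                    name=name,
                    q0=0.01 * np.array(geom["q0"]),
                    via=None if geom["via"] is None else 0.01 * np.array(geom["via"]),
                    p0=0.01 * np.array(geom["p0"]),
                    driver=drv["driver"],
                    sin_sign=drv["sin_sign"],
                    cos_sign=drv["cos_sign"],
                    cos_axis=drv["cos_axis"],
                    rod_length=0.28 if name in ("MR", "LR") else 0.20,
                )
            )
        return cls(muscles, **kwargs)

    def _apply_dz(self) -> None:
        """Shift cranial insertions (and optionally via points) along z."""
        dz = 0.01 * self.dz_cm
        if dz == 0.0:
            return
        for m in self.muscles:
            m.p0 = m.p0 + np.array([0.0, 0.0, dz])
            if self.shift_via_points and m.via is not None:
                m.via = m.via + np.array([0.0, 0.0, dz])

    def _compile(self) -> None:
        """Pack per-muscle data into arrays for the simulation inner loop."""
        ms = self.muscles
        self.Q0 = np.array([m.q0 for m in ms])                    # (6,3)
        self.P0 = np.array([m.p0 for m in ms])                    # (6,3)
        self.has_via = np.array([m.via is not None for m in ms])
        self.VIA = np.array(
            [m.via if m.via is not None else np.zeros(3) for m in ms]
        )
        self.kappa = np.array([m.kappa for m in ms])
        self.driver_idx = np.array([m.driver - 1 for m in ms])
        self.sin_sign = np.array([m.sin_sign for m in ms])
        self.cos_sign = np.array([m.cos_sign for m in ms])
        self.cos_axis = np.array([m.cos_axis for m in ms])
        self.half_rod = 0.5 * np.array([m.rod_length for m in ms])
        # length of the fixed via->P segment (0 where no via point)
        self._via_seg0 = np.where(
            self.has_via, np.linalg.norm(self.P0 - self.VIA, axis=1), 0.0
        )

    def _set_rest_lengths(self) -> None:
        l_rest = muscle_lengths(qidentity(), np.zeros(3), self)
        self.l0 = (1.0 - self.pretension) * l_rest
        for m, l0 in zip(self.muscles, self.l0):
            m.l0 = float(l0)

    def with_dz(self, dz_cm: float) -> "PlantConfig":
        """A new config with the cranial insertions shifted by ``dz_cm``.

        The shift is applied to this config's unshifted base geometry, so
        successive calls do not accumulate.
        """
        return PlantConfig(
            copy.deepcopy(self._base_muscles),
            lm=self.lm,
            lr_rod=self.lr_rod,
            chi_dyn=self.chi_dyn,
            chi_stat=self.chi_stat,
            eps_stiction=self.eps_stiction,
            inertia=self.inertia,
            dz_cm=dz_cm,
            shift_via_points=self.shift_via_points,
            pretension=self.pretension,
            dt=self.dt,
            n_substeps=self.n_substeps,
            eye_radius=self.eye_radius,
        )


# --- geometry ----------------------------------------------------------------


def driver_insertions(u: np.ndarray, cfg: PlantConfig) -> np.ndarray:
    """Cranial insertion points P_i (6,3) for driver angles u (rad)."""
    u = np.asarray(u, dtype=float)
    ui = u[cfg.driver_idx]                       # per-muscle driver angle
    P = cfg.P0.copy()
    P[:, 0] += cfg.sin_sign * cfg.half_rod * np.sin(ui)
    move = cfg.cos_sign * cfg.half_rod * (1.0 - np.cos(ui))
    P[np.arange(6), cfg.cos_axis] += move
    return P


def eye_insertions(q: np.ndarray, cfg: PlantConfig) -> np.ndarray:
    """Globe insertion points Q_i = R(q) Q0_i (6,3)."""
    R = rotmat_from_quat(q)
    return cfg.Q0 @ R.T


def _lengths_dirs(Q: np.ndarray, P: np.ndarray, cfg: PlantConfig):
    """Path lengths and unit pulling directions at the globe.

    Via-point muscles run Q -> X -> P (X fixed, so the second segment only
    changes through P); the horizontal recti run Q -> P directly.
    """
    first_target = np.where(cfg.has_via[:, None], cfg.VIA, P)
    seg1 = first_target - Q
    seg1_len = np.linalg.norm(seg1, axis=1)
    if np.any(seg1_len < 1e-9):
        raise ValueError("degenerate tendon geometry: zero-length segment")
    t_hat = seg1 / seg1_len[:, None]
    seg2_len = np.where(
        cfg.has_via, np.linalg.norm(P - cfg.VIA, axis=1), 0.0
    )
    return seg1_len + seg2_len, t_hat


def muscle_lengths(q: np.ndarray, u: np.ndarray, cfg: PlantConfig) -> np.ndarray:
    Q = eye_insertions(q, cfg)
    P = driver_insertions(u, cfg)
    lengths, _ = _lengths_dirs(Q, P, cfg)
    return lengths


def muscle_forces(state: EyeState, cfg: PlantConfig):
    """Tendon forces on the globe.

    Returns ``(F, lengths, tensions)`` where ``F`` is (6,3) in newtons.
    Tension is kappa (l - l0) clamped at zero: a slack tendon cannot push.
    """
    Q = eye_insertions(state.q, cfg)
    P = driver_insertions(state.u, cfg)
    lengths, t_hat = _lengths_dirs(Q, P, cfg)
    tensions = np.maximum(cfg.kappa * (lengths - cfg.l0), 0.0)
    F = tensions[:, None] * t_hat
    return F, lengths, tensions


def elastic_torques(state: EyeState, cfg: PlantConfig):
    """Per-muscle elastic torques tau_i = Q_i x F_i and their sum (N m)."""
    Q = eye_insertions(state.q, cfg)
    P = driver_insertions(state.u, cfg)
    lengths, t_hat = _lengths_dirs(Q, P, cfg)
    tensions = np.maximum(cfg.kappa * (lengths - cfg.l0), 0.0)
    taus = np.cross(Q, tensions[:, None] * t_hat)
    return taus, taus.sum(axis=0)


def friction_torque(omega: np.ndarray, tau_el: np.ndarray, cfg: PlantConfig):
    """Dynamic plus static friction torque.

    tau_dyn = -chi_dyn * omega always; the static term cancels the
    compensated torque tau_comp = tau_el + tau_dyn exactly when both
    |omega| < eps and |tau_comp| < chi_stat (stiction), else it is zero.
    Returns ``(tau_fric, sticking)``.
    """
    omega = np.asarray(omega, dtype=float)
    tau_dyn = -cfg.chi_dyn * omega
    tau_comp = np.asarray(tau_el, dtype=float) + tau_dyn
    sticking = (
        np.linalg.norm(omega) < cfg.eps_stiction
        and np.linalg.norm(tau_comp) < cfg.chi_stat
    )
    tau_stat = -tau_comp if sticking else np.zeros(3)
    return tau_dyn + tau_stat, sticking


def inertia_world(q: np.ndarray, cfg: PlantConfig) -> np.ndarray:
    """Orientation-dependent inertia tensor I(R) = R I0 R^T."""
    R = rotmat_from_quat(q)
    return R @ cfg.inertia @ R.T


def angular_acceleration(
    state: EyeState, cfg: PlantConfig, include_gyroscopic: bool = False
) -> np.ndarray:
    """Angular acceleration from the rigid-body torque balance.

    alpha = I(q)^-1 (tau_el + tau_fric [- omega x (I omega)]); the gyroscopic
    cross-product term is negligible for eye-sized inertias and saccadic
    velocities (see :func:`gyroscopic_ratio`) and is off by default.
    """
    _, tau_el = elastic_torques(state, cfg)
    tau_fric, sticking = friction_torque(state.omega, tau_el, cfg)
    if sticking:
        return np.zeros(3)
    I = inertia_world(state.q, cfg)
    tau = tau_el + tau_fric
    if include_gyroscopic:
        tau = tau - np.cross(state.omega, I @ state.omega)
    return np.linalg.solve(I, tau)


def gyroscopic_ratio(
    omega: np.ndarray, alpha: np.ndarray, cfg: PlantConfig
) -> float:
    """Relative power of the neglected gyroscopic term.

    Ratio of mean squared magnitudes of |omega x (I omega)| and |I alpha|
    over the supplied trajectory samples (rows of ``omega`` and ``alpha``).
    """
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    I = cfg.inertia
    Iw = omega @ I.T
    gyro = np.cross(omega, Iw)
    Ia = alpha @ I.T
    denom = np.mean(np.sum(Ia * Ia, axis=1))
    if denom == 0.0:
        raise ValueError("all-zero angular acceleration: ratio undefined")
    return float(np.mean(np.sum(gyro * gyro, axis=1)) / denom)


# --- statics -----------------------------------------------------------------


def elastic_potential(q: np.ndarray, u: np.ndarray, cfg: PlantConfig) -> float:
    """Total elastic energy 1/2 sum kappa (l - l0)_+^2 at orientation q.

    The elastic torque is minus the orientation-gradient of this potential,
    so static equilibria are its stationary points (used by the fast static
    motor-range map).
    """
    lengths = muscle_lengths(q, u, cfg)
    stretch = np.maximum(lengths - cfg.l0, 0.0)
    return float(0.5 * np.sum(cfg.kappa * stretch**2))


def total_tension(q: np.ndarray, u: np.ndarray, cfg: PlantConfig) -> float:
    """Sum of tendon tension magnitudes (N) — the static fixation force."""
    lengths = muscle_lengths(q, u, cfg)
    return float(np.sum(np.maximum(cfg.kappa * (lengths - cfg.l0), 0.0)))


# --- serialization -----------------------------------------------------------


def save_plant(cfg: PlantConfig, path) -> None:
    """Write the plant geometry as YAML (coordinates in cm, Table-style)."""
    doc = {
        "schema": "eyeplant-plant/1",
        "rod_length_vertical_cm": round(cfg.lm * 100, 6),
        "rod_length_lateral_cm": round(cfg.lr_rod * 100, 6),
        "chi_dyn": cfg.chi_dyn,
        "chi_stat": cfg.chi_stat,
        "eps_stiction": cfg.eps_stiction,
        "pretension": cfg.pretension,
        "dz_cm": cfg.dz_cm,
        "shift_via_points": cfg.shift_via_points,
        "dt": cfg.dt,
        "n_substeps": cfg.n_substeps,
        "eye_radius_cm": round(cfg.eye_radius * 100, 6),
        "inertia_kgm2": [[float(v) for v in row] for row in cfg.inertia],
        "muscles": [
            {
                "name": m.name,
                "q0_cm": [round(float(v) * 100, 6) for v in m.q0],
                "via_cm": None
                if m.via is None
                else [round(float(v) * 100, 6) for v in m.via],
                "p0_cm": [round(float(v) * 100, 6) for v in m.p0],
                "kappa": m.kappa,
                "driver": m.driver,
                "sin_sign": m.sin_sign,
                "cos_sign": m.cos_sign,
                "cos_axis": int(m.cos_axis),
                "rod_length_cm": round(m.rod_length * 100, 6),
            }
            for m in cfg.muscles
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_plant(path) -> PlantConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    muscles = [
        MuscleSpec(
            name=m["name"],
            q0=0.01 * np.array(m["q0_cm"], dtype=float),
            via=None if m["via_cm"] is None else 0.01 * np.array(m["via_cm"], float),
            p0=0.01 * np.array(m["p0_cm"], dtype=float),
            kappa=float(m["kappa"]),
            driver=int(m["driver"]),
            sin_sign=float(m["sin_sign"]),
            cos_sign=float(m["cos_sign"]),
            cos_axis=int(m["cos_axis"]),
            rod_length=0.01 * float(m["rod_length_cm"]),
        )
        for m in doc["muscles"]
    ]
    return PlantConfig(
        muscles,
        lm=0.01 * doc["rod_length_vertical_cm"],
        lr_rod=0.01 * doc["rod_length_lateral_cm"],
        chi_dyn=doc["chi_dyn"],
        chi_stat=doc["chi_stat"],
        eps_stiction=doc["eps_stiction"],
        inertia=np.array(doc["inertia_kgm2"], dtype=float),
        dz_cm=0.0,  # geometry in the file already includes any shift
        shift_via_points=doc["shift_via_points"],
        pretension=doc["pretension"],
        dt=doc["dt"],
        n_substeps=doc["n_substeps"],
        eye_radius=0.01 * doc["eye_radius_cm"],
    )
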