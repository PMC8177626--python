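"""Population analyses of simulated saccades.

Covers the standard oculomotor summaries: best-fit Listing plane and its
torsional width, the Listing-frame coordinate transform, per-saccade metrics
(amplitude, duration, peak velocity, straightness), saturating main-sequence
fits, component-stretching correlation, and the amplitude vs. peak-velocity x
duration relation.

Conventions: orientations are half-radian rotation vectors; torsional widths
are reported in degrees using the small-angle factor 2*(180/pi) on
half-radian residuals; saccade amplitude is the exact single-axis rotation
angle between start and end orientation (quaternion geodesic), not the
Euclidean norm of the rotation-vector difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from . import kinematics as kin

__all__ = [
    "PlaneFit",
    "MainSequenceFit",
    "SaccadeMetrics",
    "fit_listing_plane",
    "listing_transform",
    "saccade_metrics",
    "fit_main_sequence",
    "component_stretch_corr",
    "vpk_duration_relation",
    "table3_report",
    "HALFRAD_TO_DEG",
]

#: small-angle conversion of half-radian residuals to degrees
HALFRAD_TO_DEG = 2.0 * 180.0 / np.pi


@dataclass
class PlaneFit:
    """Least-squares plane rx = a ry + b rz through rotation-vector data."""

    a: float
    b: float
    normal: np.ndarray        # unit normal, proportional to (1, -a, -b)
    angle_deg: float          # angle between the normal and P = (1,0,0)
    width_deg: float          # SD of torsional residuals, in degrees
    n_points: int

    @property
    def pitch_deg(self) -> float:
        """Tilt of the plane seen in the (rx, rz) view, atan2(nz, nx)."""
        return float(np.degrees(np.arctan2(self.normal[2], self.normal[0])))


def fit_listing_plane(orientations: np.ndarray) -> PlaneFit:
    """Fit the displacement plane rx = a ry + b rz (no intercept).

    ``orientations`` is (N, 3) rotation vectors.  The torsional width is the
    standard deviation of the residuals, converted to degrees.
    """
    R = np.asarray(orientations, dtype=float)
    if R.ndim != 2 or R.shape[1] != 3 or len(R) < 3:
        raise ValueError("need at least 3 rotation vectors")
    X = R[:, 1:]
    if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-12) < 2 and len(R) > 3:
        raise ValueError("degenerate (collinear) orientation data")
    coef, *_ = np.linalg.lstsq(X, R[:, 0], rcond=None)
    a, b = coef
    resid = R[:, 0] - X @ coef
    n = np.array([1.0, -a, -b])
    n /= np.linalg.norm(n)
    return PlaneFit(
        a=float(a),
        b=float(b),
        normal=n,
        angle_deg=float(np.degrees(np.arccos(np.clip(n[0], -1.0, 1.0)))),
        width_deg=float(np.std(resid) * HALFRAD_TO_DEG),
        n_points=len(R),
    )


def listing_transform(orientations: np.ndarray, fit: PlaneFit) -> np.ndarray:
    """Express rotation vectors in the Listing frame of the fitted plane.

    Applies r_L = R_P r with R_P the rotation taking the fitted normal onto
    the primary direction (1, 0, 0).
    """
    _, _, RP = kin.listing_frame(fit.normal)
    return np.asarray(orientations, dtype=float) @ RP.T


@dataclass
class SaccadeMetrics:
    """Per-saccade kinematic summary."""

    amplitude_deg: float       # single-axis rotation angle start -> end
    duration_ms: float         # planned duration (ticks * dt)
    vpk_deg_s: float           # peak |omega| over the movement window
    straightness: float        # Pearson rho of (v_y, v_z) over the window
    vpk_y_deg_s: float
    vpk_z_deg_s: float
    is_fixation: bool


def saccade_metrics(traj, planned_D: int, dt: float = 0.01) -> SaccadeMetrics:
    """Metrics of one simulated saccade.

    ``traj`` is a simulator Trajectory (the replayed plan, possibly with a
    settle tail); the movement window is the planned [0, D] interval.
    Component velocities are rotation-vector rates converted with the
    small-angle factor; the peak speed uses the simulator's exact angular
    velocity.
    """
    if len(traj.t) < planned_D + 1:
        raise ValueError("trajectory shorter than the planned duration")
    q0, q1 = traj.q[0], traj.q[-1]
    dq = kin.qmult(q1, kin.qconj(q0))
    amp = float(np.degrees(2.0 * np.arctan2(np.linalg.norm(dq[1:]), abs(dq[0]))))
    win = slice(0, planned_D + 1)
    speed = np.linalg.norm(traj.omega[win], axis=1)
    vpk = float(np.degrees(speed.max()))
    v = np.diff(traj.r[: planned_D + 1], axis=0) / dt   # half-rad/s
    v_deg = v * HALFRAD_TO_DEG
    # align profile signs with the net component displacements so that a
    # straight saccade scores +1 in every direction
    disp = traj.r[planned_D] - traj.r[0]
    sy = 1.0 if disp[1] >= 0 else -1.0
    sz = 1.0 if disp[2] >= 0 else -1.0
    vy, vz = sy * v_deg[:, 1], sz * v_deg[:, 2]
    if np.std(vy) < 1e-9 or np.std(vz) < 1e-9:
        straight = 1.0  # a cardinal saccade is trivially straight
    else:
        straight = float(pearsonr(vy, vz)[0])
    return SaccadeMetrics(
        amplitude_deg=amp,
        duration_ms=planned_D * dt * 1000.0,
        vpk_deg_s=vpk,
        straightness=straight,
        vpk_y_deg_s=float(np.abs(vy).max()),
        vpk_z_deg_s=float(np.abs(vz).max()),
        is_fixation=amp < 0.5,
    )


@dataclass
class MainSequenceFit:
    """Saturating peak-velocity fit and affine duration fit."""

    v0: float                  # asymptotic peak velocity (deg/s)
    alpha: float               # angular constant (deg)
    rms_residual: float
    duration_slope_ms_deg: float
    duration_intercept_ms: float
    n: int
    near_linear: bool = False  # alpha exceeds the amplitude range


def fit_main_sequence(
    amplitudes_deg: np.ndarray,
    vpk_deg_s: np.ndarray,
    durations_ms: np.ndarray | None = None,
) -> MainSequenceFit:
    """Fit Vpk = V0 (1 - exp(-amplitude/alpha)) and D = a*amplitude + b."""
    A = np.asarray(amplitudes_deg, dtype=float)
    V = np.asarray(vpk_deg_s, dtype=float)
    if len(A) < 8:
        raise ValueError("need at least 8 saccades for a main-sequence fit")
    if A.max() < 4.0 * max(A.min(), 1e-6):
        raise ValueError("amplitude range too narrow for a saturation fit")

    def f(x, v0, al):
        return v0 * (1.0 - np.exp(-x / al))

    p0 = (float(np.percentile(V, 90)), float(np.median(A)))
    popt, _ = curve_fit(
        f, A, V, p0=p0, bounds=([1.0, 0.1], [1e6, 1e5]), maxfev=20000
    )
    v0, alpha = popt
    resid = V - f(A, *popt)
    slope, intercept = (np.nan, np.nan)
    if durations_ms is not None:
        D = np.asarray(durations_ms, dtype=float)
        slope, intercept = np.polyfit(A, D, 1)
    return MainSequenceFit(
        v0=float(v0),
        alpha=float(alpha),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        duration_slope_ms_deg=float(slope),
        duration_intercept_ms=float(intercept),
        n=len(A),
        near_linear=bool(alpha > A.max()),
    )


def component_stretch_corr(
    phi_deg: np.ndarray, vpk_fixed_component: np.ndarray
) -> float:
    """Correlation of the fixed component's peak velocity with cos(direction).

    ``phi_deg`` are saccade direction angles re. the fixed component's axis;
    a common-source vectorial drive predicts vpk proportional to cos(phi)
    (correlation +1); direction-independent peaks give ~0.
    """
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    v = np.asarray(vpk_fixed_component, dtype=float)
    if len(phi) < 5:
        raise ValueError("need at least 5 directions")
    if np.std(v) < 1e-12:
        return 0.0
    return float(pearsonr(np.cos(phi), v)[0])


def vpk_duration_relation(
    amplitudes_deg: np.ndarray,
    vpk_deg_s: np.ndarray,
    durations_ms: np.ndarray,
) -> dict:
    """OLS of amplitude on Vpk * D; returns slope, intercept and r^2.

    For triangular velocity profiles Vpk*D = 2*amplitude exactly (slope 1/2).
    """
    A = np.asarray(amplitudes_deg, dtype=float)
    x = np.asarray(vpk_deg_s, dtype=float) * np.asarray(durations_ms, float) / 1000.0
    if len(A) < 10:
        raise ValueError("need at least 10 saccades")
    slope, intercept = np.polyfit(x, A, 1)
    pred = slope * x + intercept
    ss_res = np.sum((A - pred) ** 2)
    ss_tot = np.sum((A - A.mean()) ** 2)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": float(1.0 - ss_res / ss_tot),
        "n": len(A),
    }


def table3_report(batch_summaries: list[dict]) -> pd.DataFrame:
    """Assemble one row per optimization strategy, Table-3 style.

    Each summary dict should carry: name, plane (PlaneFit), ms
    (MainSequenceFit or None), rcs (float or None), and optionally dz_cm.
    """
    rows = []
    for s in batch_summaries:
        plane: PlaneFit | None = s.get("plane")
        ms: MainSequenceFit | None = s.get("ms")
        rows.append(
            {
                "strategy": s["name"],
                "dz_cm": s.get("dz_cm", 0.0),
                "n_x": plane.normal[0] if plane else np.nan,
                "n_y": plane.normal[1] if plane else np.nan,
                "n_z": plane.normal[2] if plane else np.nan,
                "angle_to_P_deg": plane.angle_deg if plane else np.nan,
                "width_deg": plane.width_deg if plane else np.nan,
                "V0_deg_s": ms.v0 if ms else np.nan,
                "alpha_deg": ms.alpha if ms else np.nan,
                "r_cs": s.get("rcs", np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strategy", "dz_cm", "n_x", "n_y", "n_z",
            "angle_to_P_deg", "width_deg", "V0_deg_s", "alpha_deg", "r_cs",
        ],
    )
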