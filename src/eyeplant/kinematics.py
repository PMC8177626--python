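"""3D rotational kinematics for eye orientations.

Orientations are parametrized either by unit quaternions ``q = (q0, qx, qy, qz)``
(scalar part first) or by Euler-Rodrigues rotation vectors
``r = tan(rho/2) * n_hat`` in *half-radian* units, where ``rho`` is the
single-axis rotation angle about the unit axis ``n_hat``.

Axis conventions (right-handed, head-fixed primary frame):

* +x — torsion (roll), positive clockwise from the subject's view;
* +y — vertical (pitch), positive downward;
* +z — horizontal (yaw), positive leftward.

All internal angles are in radians; helpers are provided for the half-radian
rotation-vector <-> degree conversion used at I/O boundaries
(``rho = 2 atan(|r|)``).  Quaternions are canonicalized to ``q0 >= 0`` so that
the quaternion <-> rotation-vector conversion is single-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "qmult",
    "qconj",
    "qnormalize",
    "qidentity",
    "quat_from_axis_angle",
    "quat_to_rotvec",
    "rotvec_to_quat",
    "rotmat_from_quat",
    "rotvec_angle_deg",
    "deg_components_to_rotvec",
    "rotvec_to_deg_components",
    "qdot_from_omega",
    "omega_from_qdot",
    "rotvec_rate",
    "omega_from_rotvec_rate",
    "SaccadeAxis",
    "saccade_axis",
    "straight_path",
    "slerp_path",
    "listing_frame",
]

_UNIT_TOL = 1e-6


def _check_unit(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"quaternion must have 4 components, got shape {q.shape}")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > _UNIT_TOL):
        raise ValueError(f"quaternion is not unit norm (|q| = {n})")
    return q


def qidentity() -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0])


def qnormalize(q: np.ndarray) -> np.ndarray:
    """Renormalize and canonicalize the sign (q0 >= 0)."""
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    if q[0] < 0.0:
        q = -q
    return q


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return np.array([q[0], -q[1], -q[2], -q[3]])


def qmult(p: np.ndarray, q: np.ndarray, *, check: bool = False) -> np.ndarray:
    """Quaternion product p*q (Hamilton convention).

    pq = p0 q0 - p.q + (p0 q + q0 p + p x q) . I.  Non-commutative in general.
    With ``check=True`` both inputs must be unit quaternions and the result is
    renormalized and sign-canonicalized.
    """
    if check:
        p = _check_unit(p)
        q = _check_unit(q)
    p0, pv = p[0], np.asarray(p[1:], dtype=float)
    q0, qv = q[0], np.asarray(q[1:], dtype=float)
    out = np.empty(4)
    out[0] = p0 * q0 - pv @ qv
    out[1:] = p0 * qv + q0 * pv + np.cross(pv, qv)
    if check:
        out = qnormalize(out)
    return out


def quat_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        return qidentity()
    axis = axis / n
    half = 0.5 * angle_rad
    return qnormalize(np.concatenate(([np.cos(half)], np.sin(half) * axis)))


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Euler-Rodrigues rotation vector r = q_vec / q0 = tan(rho/2) n_hat."""
    q = _check_unit(q)
    q0 = q[0] if q[0] != 0.0 else q[0]
    if abs(q0) < 1e-12:
        raise ValueError("rotation angle is 180 deg; rotation vector undefined")
    if q0 < 0:
        q = -q
    return q[1:] / q[0]


def rotvec_to_quat(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    q0 = 1.0 / np.sqrt(1.0 + r @ r)
    return np.concatenate(([q0], q0 * r))


def rotmat_from_quat(q: np.ndarray) -> np.ndarray:
    """Rotation matrix R with v' = R v for the rotation encoded by q."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotvec_angle_deg(r: np.ndarray) -> float:
    """Total single-axis rotation angle in degrees, rho = 2 atan(|r|)."""
    r = np.asarray(r, dtype=float)
    return float(np.degrees(2.0 * np.arctan(np.linalg.norm(r, axis=-1))))


def deg_components_to_rotvec(deg: np.ndarray) -> np.ndarray:
    """Component-wise degrees -> half-radian rotation-vector components.

    Uses tan(theta/2) per component; exact for cardinal-axis rotations and the
    standard small-angle I/O convention otherwise.
    """
    deg = np.asarray(deg, dtype=float)
    return np.tan(np.radians(deg) / 2.0)


def rotvec_to_deg_components(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return np.degrees(2.0 * np.arctan(r))


# --- angular velocity maps ---------------------------------------------------


def qdot_from_omega(q: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Coordinate velocity q_dot = (omega q)/2 with omega a pure quaternion.

    ``omega`` is the angular velocity in the head-fixed frame (rad/s).
    """
    q = _check_unit(q)
    w = np.concatenate(([0.0], np.asarray(omega, dtype=float)))
    return 0.5 * qmult(w, q)


def omega_from_qdot(q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
    """Inverse map omega = 2 q_dot q^-1 (imaginary part)."""
    q = _check_unit(q)
    w = 2.0 * qmult(np.asarray(qdot, dtype=float), qconj(q))
    return w[1:]


def rotvec_rate(r: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Rotation-vector rate, r_dot ~= (omega + omega x r + (omega.r) r)/2.

    Accurate to O(rho^3); exact at the origin where r_dot = omega/2.
    """
    r = np.asarray(r, dtype=float)
    w = np.asarray(omega, dtype=float)
    return 0.5 * (w + np.cross(w, r) + (w @ r) * r)


def omega_from_rotvec_rate(r: np.ndarray, rdot: np.ndarray) -> np.ndarray:
    """Approximate inverse of :func:`rotvec_rate`: omega ~= 2(r_dot + r x r_dot)."""
    r = np.asarray(r, dtype=float)
    rdot = np.asarray(rdot, dtype=float)
    return 2.0 * (rdot + np.cross(r, rdot))


# --- saccade geometry --------------------------------------------------------


@dataclass(frozen=True)
class SaccadeAxis:
    """Single-axis rotation increment for a saccade between two orientations.

    Attributes
    ----------
    s : the saccade rotation-vector increment, s ~= d + rA x d (half-radians)
    d : plain difference vector rB - rA
    tilt : angle (radians) by which s tilts out of Listing's plane (x = 0)
    """

    s: np.ndarray
    d: np.ndarray
    tilt: float


def saccade_axis(rA: np.ndarray, rB: np.ndarray) -> SaccadeAxis:
    rA = np.asarray(rA, dtype=float)
    rB = np.asarray(rB, dtype=float)
    d = rB - rA
    s = d + np.cross(rA, d)
    ns = np.linalg.norm(s)
    tilt = 0.0 if ns == 0.0 else float(np.arcsin(np.clip(s[0] / ns, -1.0, 1.0)))
    return SaccadeAxis(s=s, d=d, tilt=tilt)


def straight_path(rA: np.ndarray, d: np.ndarray, sigma: float) -> np.ndarray:
    """Straight-line rotation-vector path r(sigma) = rA + sigma d, sigma in [0,1]."""
    if not 0.0 <= sigma <= 1.0:
        raise ValueError(f"sigma must lie in [0, 1], got {sigma}")
    return np.asarray(rA, dtype=float) + sigma * np.asarray(d, dtype=float)


def slerp_path(rA: np.ndarray, rB: np.ndarray, sigma: float) -> np.ndarray:
    """Exact single-axis interpolation between two orientations.

    Returns the rotation vector at fraction ``sigma`` of the constant-axis
    rotation taking orientation rA to rB.  Serves as the exact reference for
    the straight-line approximation of :func:`straight_path`.
    """
    qA = rotvec_to_quat(rA)
    qB = rotvec_to_quat(rB)
    dq = qmult(qB, qconj(qA))
    dq = qnormalize(dq)
    angle = 2.0 * np.arctan2(np.linalg.norm(dq[1:]), dq[0])
    if angle < 1e-15:
        return np.asarray(rA, dtype=float).copy()
    axis = dq[1:] / np.linalg.norm(dq[1:])
    qs = quat_from_axis_angle(axis, sigma * angle)
    return quat_to_rotvec(qnormalize(qmult(qs, qA)))


def listing_frame(normal: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Rotation taking a fitted plane normal onto the primary direction.

    Given the unit normal ``n_hat`` of a best-fit displacement plane, returns
    ``(axis, angle, R)`` where ``axis = normalize(n_hat x P)``,
    ``angle = arccos(n_hat . P)`` with ``P = (1, 0, 0)``, and ``R`` is the
    rotation matrix with ``R @ n_hat = P``.  Applying ``R`` to rotation
    vectors expresses them in the Listing frame (r_L = R r).
    """
    n = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("normal must be a unit vector")
    P = np.array([1.0, 0.0, 0.0])
    cross = np.cross(n, P)
    sin_a = np.linalg.norm(cross)
    angle = float(np.arccos(np.clip(n @ P, -1.0, 1.0)))
    if sin_a < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0, np.eye(3)
    axis = cross / sin_a
    R = rotmat_from_quat(quat_from_axis_angle(axis, angle))
    return axis, angle, R
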