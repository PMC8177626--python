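"""Linear system identification of the eye plant around the origin.

A three-channel pseudo-random binary sequence (PRBS) drives the nonlinear
simulator; a 6th-order discrete linear state-space model

    x[t+1] = A x[t] + B u[t]
    r[t]   = C x[t] + E u[t]

is then fitted by deterministic MOESP-style subspace identification
(block-Hankel data matrices, LQ factorization, SVD truncation at order n,
least squares for B, E and the initial state).  The state dimension is fixed
at 6 (three orientation plus three angular-velocity degrees of freedom).
Model quality is reported as the NRMSE fitness

    NRMSE(%) = 100 (1 - ||r - r_hat|| / ||r - r_bar||)

per output channel on a held-out validation segment (100% = perfect,
0% = mean predictor; negative values are possible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import qr, solve_discrete_lyapunov

from .rng import rng_for

__all__ = [
    "PRBSSignal",
    "LinearModel",
    "generate_prbs",
    "identify",
    "identify_arx",
    "nrmse",
    "simulate_linear",
]


@dataclass
class PRBSSignal:
    """Two-level excitation signal, one column per motor channel."""

    u: np.ndarray          # (N, 3), values in {-amplitude, +amplitude} (rad)
    dt: float
    amplitude: float
    bit_period: int        # ticks per bit
    seed: int

    @property
    def duration_s(self) -> float:
        return len(self.u) * self.dt


def generate_prbs(
    duration_s: float = 180.0,
    amplitude: float = 0.25,
    bit_period: int = 5,
    seed: int = 0,
    dt: float = 0.01,
    n_channels: int = 3,
) -> PRBSSignal:
    """Random telegraph PRBS: rectangular pulses of fixed amplitude and
    geometrically distributed duration (level redrawn each bit period),
    statistically independent across channels."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s / dt))
    n_bits = int(np.ceil(n / bit_period))
    cols = []
    for ch in range(n_channels):
        gen = rng_for(seed, f"prbs-ch{ch}")
        bits = gen.integers(0, 2, size=n_bits) * 2 - 1
        cols.append(np.repeat(bits, bit_period)[:n])
    return PRBSSignal(
        u=amplitude * np.column_stack(cols),
        dt=dt,
        amplitude=amplitude,
        bit_period=bit_period,
        seed=seed,
    )


@dataclass
class LinearModel:
    """Identified discrete state-space model at the plant's sampling tick."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    E: np.ndarray
    dt: float = 0.01
    meta: dict = field(default_factory=dict)

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    def steady_state(self, r_target: np.ndarray):
        """Holding state and input reproducing a constant output.

        Solves x = A x + B u, r = C x + E u for (x, u) given r; this is the
        operating point used to re-linearize saccade plans that start away
        from the origin.
        """
        n, m = self.order, self.B.shape[1]
        M = np.zeros((n + 3, n + m))
        M[:n, :n] = np.eye(n) - self.A
        M[:n, n:] = -self.B
        M[n:, :n] = self.C
        M[n:, n:] = self.E
        rhs = np.concatenate([np.zeros(n), np.asarray(r_target, float)])
        sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        return sol[:n], sol[n:]

    def to_json(self, path) -> None:
        doc = {
            "schema": "eyeplant-linear-model/1",
            "dt": self.dt,
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "E": self.E.tolist(),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LinearModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            A=np.array(doc["A"]),
            B=np.array(doc["B"]),
            C=np.array(doc["C"]),
            E=np.array(doc["E"]),
            dt=doc["dt"],
            meta=doc.get("meta", {}),
        )


def simulate_linear(
    model: LinearModel, U: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Free-run output of the linear model for input series U (N x m)."""
    U = np.asarray(U, dtype=float)
    n = model.order
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    Y = np.empty((len(U), model.C.shape[0]))
    A, B, C, E = model.A, model.B, model.C, model.E
    for t in range(len(U)):
        Y[t] = C @ x + E @ U[t]
        x = A @ x + B @ U[t]
    return Y


def nrmse(truth: np.ndarray, prediction: np.ndarray) -> np.ndarray:
    """NRMSE fitness (%) per output column."""
    truth = np.atleast_2d(np.asarray(truth, dtype=float).T).T
    prediction = np.atleast_2d(np.asarray(prediction, dtype=float).T).T
    if truth.shape != prediction.shape:
        raise ValueError("truth and prediction must have matching shapes")
    denom = np.linalg.norm(truth - truth.mean(axis=0), axis=0)
    if np.any(denom == 0.0):
        raise ValueError("constant truth signal: NRMSE undefined")
    num = np.linalg.norm(truth - prediction, axis=0)
    return 100.0 * (1.0 - num / denom)


def _block_hankel(data: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    """Stack ``n_rows`` shifted copies of (N, d) data into a (n_rows*d, n_cols)
    block-Hankel matrix."""
    d = data.shape[1]
    win = sliding_window_view(data, (n_rows, d)).reshape(-1, n_rows * d)
    return win[:n_cols].T.reshape(n_rows * d, n_cols)


def _fit_b_e_x0(Y, U, A, C):
    """Least-squares estimate of B, E and x0 given A and C.

    The state is affine in (x0, vec(B)): x_t = A^t x0 + G_t vec(B) with
    G_t = A G_{t-1} + kron(u_{t-1}^T, I).  Outputs are then linear in
    (x0, vec(B), vec(E)).
    """
    N, m = U.shape
    l = Y.shape[1]
    n = A.shape[0]
    G = np.zeros((n, n * m))
    Ax = np.eye(n)
    rows = np.empty((N, l, n + n * m + l * m))
    eye_l = np.eye(l)
    for t in range(N):
        rows[t, :, :n] = C @ Ax
        rows[t, :, n : n + n * m] = C @ G
        rows[t, :, n + n * m :] = np.kron(U[t], eye_l)
        if t < N - 1:
            G = A @ G + np.kron(U[t], np.eye(n))
            Ax = A @ Ax
    M = rows.reshape(N * l, -1)
    theta, *_ = np.linalg.lstsq(M, Y.reshape(-1), rcond=None)
    x0 = theta[:n]
    B = theta[n : n + n * m].reshape(m, n).T
    E = theta[n + n * m :].reshape(m, l).T
    return B, E, x0


def identify(
    inputs: np.ndarray,
    outputs: np.ndarray,
    order: int = 6,
    *,
    train_s: float = 120.0,
    dt: float = 0.01,
    hankel_rows: int = 20,
    detrend: bool = True,
    meta: dict | None = None,
) -> LinearModel:
    """Deterministic MOESP subspace identification.

    The first ``train_s`` seconds train the model; the remainder is the
    held-out validation segment on which per-output NRMSE is reported in
    ``model.meta['nrmse_validation']``.  With ``detrend`` (default) the
    training-segment means are removed from inputs and outputs before
    identification — the standard preprocessing step for subspace methods —
    and stored in ``meta['u_mean']`` / ``meta['y_mean']``.
    """
    U = np.asarray(inputs, dtype=float).copy()
    Y = np.asarray(outputs, dtype=float).copy()
    u_mean = np.zeros(U.shape[1])
    y_mean = np.zeros(Y.shape[1])
    if detrend:
        n_tr = min(int(round(train_s / dt)), len(U))
        u_mean = U[:n_tr].mean(axis=0)
        y_mean = Y[:n_tr].mean(axis=0)
        U -= u_mean
        Y -= y_mean
    if len(U) != len(Y):
        raise ValueError("inputs and outputs must be synchronized")
    if len(U) < 20 * order:
        raise ValueError(f"need at least {20 * order} samples, got {len(U)}")
    n_train = min(int(round(train_s / dt)), len(U))
    U_tr, Y_tr = U[:n_train], Y[:n_train]
    m, l = U.shape[1], Y.shape[1]
    i = hankel_rows
    j = n_train - i + 1
    Uh = _block_hankel(U_tr, i, j)
    Yh = _block_hankel(Y_tr, i, j)
    # LQ factorization of [U; Y]: the part of Y orthogonal to the input row
    # space spans the extended observability matrix.
    R = qr(np.vstack([Uh, Yh]).T, mode="economic")[1].T
    L22 = R[i * m :, i * m :]
    svd_U, svd_s, _ = np.linalg.svd(L22)
    if svd_s[order - 1] < 1e-12 * svd_s[0]:
        raise ValueError("rank-deficient data: excitation does not reach the requested order")
    gamma = svd_U[:, :order] * np.sqrt(svd_s[:order])
    C_hat = gamma[:l]
    A_hat, *_ = np.linalg.lstsq(gamma[:-l], gamma[l:], rcond=None)
    B_hat, E_hat, x0 = _fit_b_e_x0(Y_tr, U_tr, A_hat, C_hat)
    model = LinearModel(A=A_hat, B=B_hat, C=C_hat, E=E_hat, dt=dt, meta=meta or {})
    # training fit
    Y_fit = simulate_linear(model, U_tr, x0)
    model.meta["nrmse_train"] = nrmse(Y_tr, Y_fit).tolist()
    model.meta["order"] = order
    model.meta["hankel_rows"] = i
    model.meta["n_train"] = n_train
    model.meta["u_mean"] = u_mean.tolist()
    model.meta["y_mean"] = y_mean.tolist()
    if n_train < len(U):
        # propagate the estimated state to the validation boundary
        x = x0
        for t in range(n_train):
            x = A_hat @ x + B_hat @ U[t]
        Y_val = simulate_linear(model, U[n_train:], x)
        model.meta["nrmse_validation"] = nrmse(Y[n_train:], Y_val).tolist()
    return model


def identify_plant(
    cfg,
    seed: int = 1,
    *,
    duration_s: float = 180.0,
    amplitude: float = 0.25,
    bit_period: int = 5,
    order: int = 6,
    train_s: float = 120.0,
    hankel_rows: int = 20,
) -> LinearModel:
    """PRBS-excite the nonlinear plant and identify its local linear model.

    Convenience wrapper: generates the three-channel PRBS, simulates the
    plant from the primary position, and runs :func:`identify` with the
    train/validation split.  The per-output validation NRMSE lands in
    ``model.meta['nrmse_validation']``.
    """
    from .plant import EyeState
    from .simulator import simulate

    prbs = generate_prbs(duration_s, amplitude, bit_period, seed=seed, dt=cfg.dt)
    traj = simulate(prbs.u, EyeState(), cfg)
    model = identify(
        prbs.u,
        traj.r[:-1],
        order,
        train_s=train_s,
        dt=cfg.dt,
        hankel_rows=hankel_rows,
        meta={
            "prbs": {
                "duration_s": duration_s,
                "amplitude": amplitude,
                "bit_period": bit_period,
                "seed": seed,
            }
        },
    )
    return model


def identify_arx(
    inputs: np.ndarray,
    outputs: np.ndarray,
    order: int = 6,
    arx_lags: int = 8,
    *,
    train_s: float = 120.0,
    dt: float = 0.01,
) -> LinearModel:
    """High-order ARX fit reduced to ``order`` states by balanced truncation.

    An independent least-squares route used to cross-check the subspace
    estimate: fit a vector ARX model, realize it in companion form, and
    truncate the balanced realization.
    """
    U = np.asarray(inputs, dtype=float)
    Y = np.asarray(outputs, dtype=float)
    n_train = min(int(round(train_s / dt)), len(U))
    U_tr, Y_tr = U[:n_train], Y[:n_train]
    m, l = U.shape[1], Y.shape[1]
    p = arx_lags
    rows = []
    for t in range(p, n_train):
        past = [Y_tr[t - k] for k in range(1, p + 1)]
        past += [U_tr[t - k] for k in range(0, p + 1)]
        rows.append(np.concatenate(past))
    M = np.array(rows)
    theta, *_ = np.linalg.lstsq(M, Y_tr[p:], rcond=None)
    theta = theta.T  # (l, p*l + (p+1)*m)
    A_coefs = [theta[:, k * l : (k + 1) * l] for k in range(p)]
    B_coefs = [theta[:, p * l + (k * m) : p * l + (k + 1) * m] for k in range(p + 1)]
    # state = [y_{t-1};...;y_{t-p}; u_{t-1};...;u_{t-p}]
    nx = p * (l + m)
    C = np.zeros((l, nx))
    for k in range(p):
        C[:, k * l : (k + 1) * l] = A_coefs[k]
        C[:, p * l + k * m : p * l + (k + 1) * m] = B_coefs[k + 1]
    E = B_coefs[0]
    A = np.zeros((nx, nx))
    B = np.zeros((nx, m))
    A[:l] = C                                   # y_t enters the state
    B[:l] = E
    if p > 1:
        A[l : p * l, : (p - 1) * l] = np.eye((p - 1) * l)
        A[p * l + m :, p * l : p * l + (p - 1) * m] = np.eye((p - 1) * m)
    B[p * l : p * l + m] = np.eye(m)            # u_t enters the state
    # square-root balanced truncation to the requested order
    eigmax = np.max(np.abs(np.linalg.eigvals(A)))
    if eigmax >= 0.9995:
        A = A * (0.999 / eigmax)
    P = solve_discrete_lyapunov(A, B @ B.T)
    Q = solve_discrete_lyapunov(A.T, C.T @ C)
    lp, Up = np.linalg.eigh((P + P.T) / 2)
    Lp = Up * np.sqrt(np.clip(lp, 1e-14, None))
    lq, Uq = np.linalg.eigh((Q + Q.T) / 2)
    Lq = Uq * np.sqrt(np.clip(lq, 1e-14, None))
    Us, Ss, Vts = np.linalg.svd(Lq.T @ Lp)
    s_inv_sqrt = 1.0 / np.sqrt(Ss[:order])
    T = Lp @ Vts[:order].T * s_inv_sqrt
    Ti = (Us[:, :order] * s_inv_sqrt).T @ Lq.T
    model = LinearModel(
        A=Ti @ A @ T, B=Ti @ B, C=C @ T, E=E, dt=dt,
        meta={"method": "arx-balred", "arx_lags": p},
    )
    if n_train < len(U):
        B_f, E_f, x0 = _fit_b_e_x0(Y_tr, U_tr, model.A, model.C)
        model.B, model.E = B_f, E_f
        x = x0
        for t in range(n_train):
            x = model.A @ x + B_f @ U[t]
        Y_val = simulate_linear(model, U[n_train:], x)
        model.meta["nrmse_validation"] = nrmse(Y[n_train:], Y_val).tolist()
    return model
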