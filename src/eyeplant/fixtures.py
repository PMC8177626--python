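"""Deterministic fixture generators for tests and demos.

Each generator is seeded and writes plain-text artifacts (JSON/YAML/CSV):

* ``linear-system`` — a random stable 6-state discrete model (the oracle for
  the subspace-identification round trip);
* ``rotvec-cloud`` — rotation vectors scattered around a plane with a chosen
  normal and torsional SD (the oracle for the plane-fit width recovery);
* ``triangular-saccades`` — analytic triangular-velocity-profile
  trajectories, for which Vpk * D = 2 * amplitude exactly;
* ``table1-plant`` — the default plant geometry serialized to YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from .plant import PlantConfig, save_plant
from .rng import rng_for
from .sysid import LinearModel

__all__ = [
    "make_linear_system",
    "make_rotvec_cloud",
    "make_triangular_saccades",
    "make_fixtures",
]

KINDS = ("linear-system", "rotvec-cloud", "triangular-saccades", "table1-plant")


def make_linear_system(
    seed: int = 0, order: int = 6, n_inputs: int = 3, n_outputs: int = 3,
    spectral_radius: float = 0.9,
) -> LinearModel:
    """Random stable discrete state-space system."""
    g = rng_for(seed, "fixture-linear-system")
    A = g.normal(size=(order, order))
    A *= spectral_radius / np.max(np.abs(np.linalg.eigvals(A)))
    B = g.normal(size=(order, n_inputs))
    C = g.normal(size=(n_outputs, order))
    E = 0.1 * g.normal(size=(n_outputs, n_inputs))
    return LinearModel(A=A, B=B, C=C, E=E, meta={"fixture": True, "seed": seed})


def make_rotvec_cloud(
    seed: int = 0,
    n: int = 2000,
    normal: np.ndarray | None = None,
    torsional_sd_halfrad: float = 0.015,
    gaze_sd_halfrad: float = 0.15,
) -> np.ndarray:
    """Rotation vectors around a plane with controlled torsional scatter.

    Points are drawn in the plane's own frame (x = 0 plus Gaussian torsional
    noise of SD ``torsional_sd_halfrad``) and rotated so the plane normal
    becomes ``normal``.
    """
    g = rng_for(seed, "fixture-rotvec-cloud")
    pts = np.column_stack(
        [
            g.normal(0.0, torsional_sd_halfrad, n),
            g.normal(0.0, gaze_sd_halfrad, n),
            g.normal(0.0, gaze_sd_halfrad, n),
        ]
    )
    if normal is not None:
        n_hat = np.asarray(normal, float)
        n_hat = n_hat / np.linalg.norm(n_hat)
        # rotation taking (1,0,0) onto n_hat = inverse of the Listing map
        _, _, R = kin.listing_frame(n_hat)
        pts = pts @ R  # R^T applied row-wise: inverse transform
    return pts


def make_triangular_saccades(
    seed: int = 0, n: int = 40, dt: float = 0.01
) -> pd.DataFrame:
    """Analytic saccades with triangular velocity profiles.

    Peak velocity times duration equals exactly twice the amplitude — the
    closed-form anchor for the amplitude vs. Vpk*D regression.
    """
    g = rng_for(seed, "fixture-triangular")
    rows = []
    for i in range(n):
        amp = g.uniform(2.0, 40.0)                 # deg
        D_ticks = 2 * g.integers(2, 16)            # even tick count
        D = D_ticks * dt
        vpk = 2.0 * amp / D
        rows.append(
            {
                "index": i,
                "amplitude_deg": amp,
                "duration_ms": D * 1000.0,
                "vpk_deg_s": vpk,
            }
        )
    return pd.DataFrame(rows)


def make_fixtures(kind: str, seed: int, outdir) -> Path:
    """Write one fixture kind to ``outdir``; returns the file path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "linear-system":
        path = outdir / f"linear_system_seed{seed}.json"
        make_linear_system(seed).to_json(path)
    elif kind == "rotvec-cloud":
        path = outdir / f"rotvec_cloud_seed{seed}.csv"
        pts = make_rotvec_cloud(seed)
        pd.DataFrame(pts, columns=["rx", "ry", "rz"]).to_csv(path, index=False)
    elif kind == "triangular-saccades":
        path = outdir / f"triangular_saccades_seed{seed}.csv"
        make_triangular_saccades(seed).to_csv(path, index=False)
    elif kind == "table1-plant":
        path = outdir / "table1.yaml"
        save_plant(PlantConfig.table1(), path)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")
    return path
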