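"""Rest-pose mechanics of the tendon-driven eye plant.

Builds the default six-muscle geometry and prints each tendon's normalized
torque direction at the primary position.  The horizontal recti (MR, LR)
pull almost purely about the vertical axis (tau_z ~ +/-1); the vertical
recti and obliques mix strong torsional and vertical components — the
anatomical reason vertical saccades need coordinated drive.
"""

import numpy as np

from eyeplant.plant import EyeState, PlantConfig, elastic_torques

cfg = PlantConfig.table1()
taus, total = elastic_torques(EyeState(), cfg)
dirs = taus / np.linalg.norm(taus, axis=1, keepdims=True)

print("muscle   tau_x   tau_y   tau_z   (normalized torque direction at rest)")
for m, d in zip(cfg.muscles, dirs):
    print(f"{m.name:6s} {d[0]:+7.3f} {d[1]:+7.3f} {d[2]:+7.3f}")
print(f"\nnet rest torque magnitude: {np.linalg.norm(total):.2e} N m "
      f"(stiction threshold {cfg.chi_stat} N m -> the origin is an equilibrium)")
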