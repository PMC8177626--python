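"""Step response of the nonlinear simulator.

Applies a constant 0.1 rad command to the horizontal driver and prints the
eye's horizontal orientation over the first second.  The plant is
overdamped: the orientation approaches its new equilibrium monotonically
(gain ~1.5 deg of eye rotation per deg of driver rotation) and freezes
inside the static-friction band.
"""

import numpy as np

from eyeplant.plant import EyeState, PlantConfig
from eyeplant.simulator import simulate

cfg = PlantConfig.table1()
U = np.tile([0.0, 0.1, 0.0], (100, 1))          # 1 s at the 10 ms tick
traj = simulate(U, EyeState(), cfg)

deg = np.degrees(2 * np.arctan(traj.r[:, 2]))
for i in range(0, 101, 10):
    print(f"t = {traj.t[i]:.2f} s   horizontal = {deg[i]:6.2f} deg   "
          f"omega_z = {np.degrees(traj.omega[i, 2]):7.1f} deg/s")
print(f"\nfinal orientation {deg[-1]:.2f} deg for a {np.degrees(0.1):.2f} deg "
      f"driver step (static gain ~{deg[-1]/np.degrees(0.1):.2f})")
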