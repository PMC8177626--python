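"""Emergence of Listing's law from the cost functional.

Runs two small chained batches of random saccades (Gaussian component SD
15 deg) and fits the best-fit plane rx = a*ry + b*rz through all visited
orientations.  Under the plain AED cost the torsional scatter is wide; with
the fixation-force term added (penalizing total static tendon tension at
the endpoint) the orientations collapse onto a thin, nearly torsion-free
plane — Listing's law as an emergent property.
"""

import numpy as np

from eyeplant.control import CostWeights, estimate_force_hessian
from eyeplant.experiments import ExperimentSpec, run_batch
from eyeplant.plant import PlantConfig
from eyeplant.sysid import identify_plant

cfg = PlantConfig.table1()
model = identify_plant(cfg, seed=1)
hf = estimate_force_hessian(cfg, 7, 30.0)

for name in ("AED", "Force"):
    spec = ExperimentSpec(name, n_saccades=60, seed=1,
                          weights=CostWeights.preset(name))
    batch = run_batch(spec, model, cfg, hf=hf)
    plane = batch.plane()
    print(f"{name:6s}: torsional width {plane.width_deg:5.2f} deg, "
          f"plane normal {np.round(plane.normal, 3)}, "
          f"{plane.angle_deg:.1f} deg from straight-ahead")
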