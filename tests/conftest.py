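"""Shared fixtures.

The identified linear model, the force quadratic and the standard batches
are expensive (seconds to tens of seconds), so they are session-scoped and
shared across test modules.  Everything is generated from fixed seeds at
import-free run time; no data files are read.
"""

from __future__ import annotations

import numpy as np
import pytest

from eyeplant.control import CostWeights, estimate_force_hessian
from eyeplant.experiments import ExperimentSpec, run_batch
from eyeplant.plant import PlantConfig
from eyeplant.sysid import identify_plant


@pytest.fixture(scope="session")
def plant() -> PlantConfig:
    return PlantConfig.table1()


@pytest.fixture(scope="session")
def model(plant):
    """Default-settings identified model (PRBS seed 1)."""
    return identify_plant(plant, seed=1)


@pytest.fixture(scope="session")
def force_quadratic(plant):
    return estimate_force_hessian(plant, 7, 30.0)


@pytest.fixture(scope="session")
def batches(model, plant, force_quadratic):
    """Chained random-saccade batches per functional, matched seeds.

    n = 300 for the strategies graded on population statistics; the
    torsional-width and main-sequence checks read from here.
    """
    out = {}
    for name, n in [
        ("AED", 300), ("AEDL1", 300), ("Force", 300),
        ("AEDL2", 150), ("AE", 150),
    ]:
        spec = ExperimentSpec(name, n_saccades=n, seed=1,
                              weights=CostWeights.preset(name))
        out[name] = run_batch(spec, model, plant, hf=force_quadratic)
    return out
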