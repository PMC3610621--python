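"""Shared fixtures.

The heavy simulations (the calibrated baseline run and the spherically
symmetric oracle pair) are session-scoped so the acceptance tests that share
a run do not recompute it.
"""

from __future__ import annotations

import numpy as np
import pytest

from lymphsim import (IHCCalibration, LymphomaGrowthModel, ModelParameters,
                      SphericalTumorModel, synth_ihc)

BASELINE_SEED = 1


@pytest.fixture(scope="session")
def baseline_params() -> ModelParameters:
    """Planar full-resolution baseline: 64^2 at 100 µm, days 9-21."""
    return ModelParameters(dim=2, spacing_um=100.0)


@pytest.fixture(scope="session")
def baseline_run(baseline_params):
    """Calibrated baseline simulation via the IHC fixed point (Day 9 -> 21)."""
    table = synth_ihc("baseline", rng=BASELINE_SEED)
    fit, sim = IHCCalibration(table).fit_with_simulation(
        baseline_params, seed=BASELINE_SEED)
    return fit, sim


@pytest.fixture(scope="session")
def oracle_pair():
    """Spherically symmetric core-supply run: 3D 32^3 vs the radial solver.

    The configuration is chosen so the reduced model's assumptions hold on
    the coarse grid: the substrate boundary layer (600 µm) is resolved at
    h = 200 µm, the outward-starved front stays sharp without adhesion, and
    the seed sits near the supported stationary radius.
    """
    p = ModelParameters(dim=3, spacing_um=200.0, seed_radius_mm=0.85,
                        root_radius_mm=0.6, L_hypoxia_um=600.0, gamma=0.0)
    model = LymphomaGrowthModel(p, supply_mode="core")
    res3d = model.simulate(seed=0)
    nvox = int((model.grid.radius_from() <= p.root_radius_mm).sum())
    a_eff = (3.0 * nvox * model.grid.cell_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    radial = SphericalTumorModel(p.replace(root_radius_mm=a_eff), supply="core")
    res1d = radial.run(R0_mm=res3d.trajectory["diameter_mm"].iloc[0] / 2.0)
    return res3d, res1d
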