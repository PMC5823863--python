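import numpy as np
import pytest

from micropk import correlator, fcs_models, synthetic

# shared geometry of the default instrument world
W0 = 0.2e-6
Z0 = 1.0e-6
S = 5.0
V_EFF_L = float(np.pi ** 1.5 * W0**2 * Z0 * 1e3)     # gaussian convention
BOX_HALF = (4 * W0, 4 * W0, 4 * Z0)
V_BOX_L = float(8 * W0 * 8 * W0 * 8 * Z0 * 1e3)
A_EFF = float(np.pi * W0**2)
AREA_BOX = float(8 * W0 * 8 * W0)
TAU_D_3D = 140e-6


@pytest.fixture(scope="session")
def solution_trace():
    """One medium-length 1.8 nM solution trace, reused across tests."""
    cfg = synthetic.SolutionSimConfig(concentration=1.8, duration=10.0, seed=42)
    return synthetic.simulate_solution_trace(cfg)


@pytest.fixture(scope="session")
def solution_fit(solution_trace):
    acf = correlator.multitau_autocorrelate(solution_trace)
    tpl = fcs_models.FCSModelSpec.single_3d(1.0, 1e-4, S)
    return fcs_models.fit_acf(acf, tpl)


def realized_n_eff_3d(trace) -> float:
    """Particle number in V_eff implied by the trace's realized box count."""
    return trace.metadata["n_particles_3d"] * V_EFF_L / V_BOX_L


def realized_n_eff_2d(trace) -> float:
    return trace.metadata["n_particles_2d"] * A_EFF / AREA_BOX
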