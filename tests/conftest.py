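import numpy as np
import pytest

from memdpd import (DPDSimulation, ForceFieldParams, MembraneSpec,
                    SimulationState, assemble_bilayer)


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParams.default()


@pytest.fixture()
def fluid_state():
    """Small homogeneous water fluid at rho = 3, box 6^3."""
    rng = np.random.default_rng(7)
    n = 648
    box = np.array([6.0, 6.0, 6.0])
    st = SimulationState(
        positions=rng.uniform(0, box, (n, 3)),
        velocities=rng.normal(size=(n, 3)),
        species=np.zeros(n, dtype=int),
        molecule_id=np.arange(n),
        box=box,
    )
    st.velocities -= st.velocities.mean(axis=0)
    return st


@pytest.fixture(scope="session")
def small_bilayer():
    """Assembled (not equilibrated) 6x6 bilayer patch."""
    spec = MembraneSpec(nx=6, ny=6, box_height=8.0)
    return assemble_bilayer(spec, seed=5)
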