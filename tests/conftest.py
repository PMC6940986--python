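import numpy as np
import pytest

import saxshybrid as sx


@pytest.fixture(scope="session")
def q_grid():
    """Instrument-like q grid, 0.004-0.42 1/A."""
    return np.linspace(0.004, 0.42, 256)


@pytest.fixture(scope="session")
def sphere_model():
    """Dense bead sphere, R = 20 A."""
    return sx.generate_structure(
        sx.ToyStructureSpec(shape="sphere", radius=20.0, n_beads=2000))


@pytest.fixture(scope="session")
def sphere_curve(sphere_model, q_grid):
    """Noiseless sphere curve with the default SEC-SAXS noise model sigmas."""
    return sx.simulate_curve(sphere_model, q_grid).noiseless


@pytest.fixture(scope="session")
def dimer_dataset(q_grid):
    """Flat two-domain C2 dimer and its simulated curves."""
    model = sx.generate_structure(sx.ToyStructureSpec(twist_deg=0.0, phi_deg=40.0))
    return sx.simulate_curve(model, q_grid, sx.NoiseSpec(seed=11))


@pytest.fixture(scope="session")
def search_q():
    """Coarser grid used by rigid-body search tests."""
    return np.linspace(0.01, 0.30, 150)
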