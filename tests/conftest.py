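import numpy as np
import pytest

from ucrefine.model import UnitCellGeometry
from ucrefine.toys import ToySpec, make_toy_crystal, simulate_f_obs


@pytest.fixture(scope="session")
def p21_toy():
    """Standard monoclinic toy: 24-atom ASU, 48-atom cell, noiseless data."""
    spec = ToySpec(seed=3)
    model = make_toy_crystal(spec)
    rset = simulate_f_obs(model, spec)
    return spec, model, rset


@pytest.fixture(scope="session")
def small_toy():
    """Tiny 20-atom-cell toy for finite-difference and gradient work."""
    spec = ToySpec(seed=5, n_atoms=10, d_min=2.2, n_shells=4, chain_len=5)
    model = make_toy_crystal(spec)
    rset = simulate_f_obs(model, spec)
    return spec, model, rset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def cubic_cell():
    return UnitCellGeometry(10.0, 10.0, 10.0)
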