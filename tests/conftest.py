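import numpy as np
import pytest

from cavsolv.energetics import InteractionModel
from cavsolv.synthetic import GeneratorConfig, build_topology, gen_ideal_gas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model():
    """Interaction model matching the synthetic solvent, short cutoff."""
    return InteractionModel(cutoff=6.0, e_neat=0.0, rho0=0.0334)


@pytest.fixture
def water_box():
    """20 interacting waters, 5 random frames (for oracle comparisons)."""
    cfg = GeneratorConfig(n_waters=20, box=(10.0, 10.0, 10.0), n_frames=5, seed=7)
    return gen_ideal_gas(cfg)


@pytest.fixture
def ideal_gas_traj():
    """Zero-parameter waters, uniform placements."""
    cfg = GeneratorConfig(n_waters=30, box=(12.0, 12.0, 12.0), n_frames=40, seed=11)
    return gen_ideal_gas(cfg, zero_parameters=True)


@pytest.fixture
def bare_water_topology():
    return build_topology(1)
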