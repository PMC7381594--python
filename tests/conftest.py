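import numpy as np
import pandas as pd
import pytest

from frillmorph.superimposition import gpa
from frillmorph.synthetic_data import (
    SimulationConfig,
    default_timetree,
    simulate_tip_shapes,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def timetree(sim_config):
    return default_timetree(sim_config)


@pytest.fixture(scope="session")
def tip_shapes(sim_config, timetree):
    return simulate_tip_shapes(sim_config, timetree)


@pytest.fixture(scope="session")
def aligned_sample(tip_shapes):
    return gpa(list(tip_shapes.values()))


@pytest.fixture(scope="session")
def species_shape_matrix(tip_shapes, aligned_sample):
    species = [c.species for c in tip_shapes.values()]
    return pd.DataFrame(aligned_sample.shapes, index=species)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
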