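import numpy as np
import pytest

from oriem import CONDITIONS, generate_session_design
from oriem.simulate import SimulationConfig, simulate_epochs


@pytest.fixture(scope="session")
def small_design():
    """Two balanced 45-trial blocks (smallest size meeting all divisibility)."""
    return generate_session_design(n_blocks=2, trials_per_block=45, seed=3)


def make_config(**kw):
    defaults = dict(n_subjects=1, n_blocks=2, trials_per_block=45,
                    intersubject_gain_sd=0.0, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_epochs(small_design):
    """Unit-gain, zero-noise simulation: exact round trips."""
    cfg = make_config(noise_sd_uV=0.0, pink_noise_sd_uV=0.0,
                      tuning_gain_by_condition={c: 1.0 for c in CONDITIONS})
    return simulate_epochs(small_design, cfg)


@pytest.fixture(scope="session")
def noisy_epochs(small_design):
    """Default-gain simulation with the generator's standard noise levels."""
    cfg = make_config()
    return simulate_epochs(small_design, cfg)
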