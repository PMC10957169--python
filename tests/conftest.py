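import numpy as np
import pytest

from latent_avalanches import SimulationConfig, draw_couplings


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_quasistatic_config():
    return SimulationConfig(
        n_neurons=64,
        n_fields=1,
        eta=3.0,
        epsilon=5.0,
        tau_F="quasistatic",
        n_steps=50_000,
        n_segments=10,
        seed=7,
    )


@pytest.fixture
def coupling_column(rng):
    """A fixed 128-neuron single-field coupling column."""
    cfg = SimulationConfig(
        n_neurons=128, n_fields=1, eta=1.0, epsilon=0.0, tau_F=1.0, n_steps=1, seed=0
    )
    return draw_couplings(cfg, rng)
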