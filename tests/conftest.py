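import dataclasses

import pytest

from iridoptics import DISORDERED, ORDERED, MonteCarloConfig


@pytest.fixture(scope="session")
def ordered():
    return ORDERED


@pytest.fixture(scope="session")
def disordered():
    return DISORDERED


@pytest.fixture
def zero_variance_ordered():
    """Ordered preset with all randomness removed (27/131 nm, 25 layers)."""
    return dataclasses.replace(
        ORDERED, crystal_thickness_sd=0.0, cytoplasm_sd=0.0,
        layer_count_min=25, layer_count_max=25,
    )


@pytest.fixture
def fast_cfg():
    """Small Monte Carlo config for quick unit tests."""
    return MonteCarloConfig(n_runs=40, wavelength_step=2.0, rng_seed=0)
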