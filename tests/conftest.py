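import pytest

from oncohistone_screen.synthetic_data import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down configuration for fast end-to-end runs."""
    return SimulationConfig(
        seed=7,
        n_samples=50,
        saml_frac=0.2,
        n_h3_mutant=4,
        mutant_saml_frac=0.5,
        depth_mean=500,
        n_genes=50,
        reads_per_library=20_000,
    )


@pytest.fixture
def paperlike_config() -> SimulationConfig:
    """The default study-condition configuration."""
    return SimulationConfig(seed=3)
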