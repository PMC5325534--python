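import pytest

from bovisnp.model import Breed, SampleMeta
from bovisnp.simulate import SimulationConfig, simulate_variant_panel


@pytest.fixture(scope="session")
def small_panel():
    """A seeded 18-sample panel small enough for exhaustive checks."""
    cfg = SimulationConfig(seed=11, n_sites=800)
    per_sample, truth = simulate_variant_panel(cfg)
    return cfg, per_sample, truth


@pytest.fixture()
def sample():
    return SampleMeta("PolishRed_6m_r1", Breed.POLISH_RED, 6, 1)


@pytest.fixture()
def sample2():
    return SampleMeta("PolishRed_6m_r2", Breed.POLISH_RED, 6, 2)
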