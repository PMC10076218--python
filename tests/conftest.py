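import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from coseq import PixelGrid, SimConfig, build_pixel_grid, make_schema, make_toy_genome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schema_atac():
    return make_schema(20, 20, modality="atac", seed=11)


@pytest.fixture(scope="session")
def schema_rna():
    return make_schema(20, 20, modality="rna", seed=11)


@pytest.fixture(scope="session")
def grid(schema_atac) -> PixelGrid:
    return build_pixel_grid(schema_atac)


@pytest.fixture(scope="session")
def toy_genome():
    """(gene models, peaks, genome length) on one toy chromosome."""
    return make_toy_genome(n_genes=15, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=42)
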