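import pytest
from hypothesis import HealthCheck, settings

import splitkit as sk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def guarantee_chem():
    """Small whitelists (12/round) at pairwise Hamming >= 6: forced correction."""
    return sk.guarantee_chemistry(seed=1)


@pytest.fixture(scope="session")
def realistic_chem():
    """96 barcodes per round at pairwise Hamming >= 3."""
    return sk.realistic_chemistry(seed=1)


@pytest.fixture(scope="session")
def layout_v2(guarantee_chem):
    return sk.build_layout(guarantee_chem)


@pytest.fixture(scope="session")
def toy_config(guarantee_chem):
    """4 cells x 80 reads, equal category mix (10 reads per category per cell)."""
    return sk.SimConfig(
        n_cells=4, reads_per_cell=80, chemistry=guarantee_chem, seed=11
    )


@pytest.fixture(scope="session")
def toy_pairs(toy_config):
    return list(sk.iter_read_pairs(toy_config))
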