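import pytest

from sbbc import SimConfig, simulate_bundle
from sbbc.relatedness import toy_breast_catalogue
from sbbc.synthetic_cohort import simulate_tumor_genomes


def small_config(**overrides) -> SimConfig:
    defaults = dict(n_pairs=60, n_sequenced_pairs=4, n_genes=400, seed=7)
    defaults.update(overrides)
    cfg = SimConfig(**defaults)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def bundle(config):
    return simulate_bundle(config)


@pytest.fixture(scope="session")
def genomes(config):
    return simulate_tumor_genomes(config)


@pytest.fixture(scope="session")
def catalogue():
    return toy_breast_catalogue()
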