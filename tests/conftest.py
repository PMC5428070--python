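import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))  # make oracles importable

from dietreg.synthetic import (  # noqa: E402
    SyntheticConfig,
    generate_gene_models,
    generate_genome,
    generate_peaks,
)


@pytest.fixture(scope="session")
def base_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def genome(base_config):
    return generate_genome(base_config)


@pytest.fixture(scope="session")
def genes(base_config, genome):
    return generate_gene_models(base_config, genome)


@pytest.fixture(scope="session")
def peaks(base_config, genes):
    return generate_peaks(base_config, genes)
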