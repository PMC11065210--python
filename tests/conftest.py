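import numpy as np
import pytest

from phenobank import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    """2 species x 2 accessions x 3 plants — the small smoke fixture."""
    return synthdata.default_config(
        n_species=2,
        accessions_per_species=2,
        plants_per_accession=3,
        image_size=96,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return synthdata.generate_dataset(tiny_config)
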