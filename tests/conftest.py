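import numpy as np
import pytest

from phenoscreen import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.GeneratorConfig(
        n_compounds=400, n_assays=6, n_clusters=25, fp_bits=256,
        fill_rate=0.6, hit_rate=0.05, n_plates=4, n_features=32,
        replicates_per_compound=2, phenotype_snr=4.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return syn.generate_library(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return syn.generate_panel(small_config)


@pytest.fixture(scope="session")
def small_labels(small_config, small_library, small_panel):
    return syn.generate_labels(small_library, small_panel, small_config)


@pytest.fixture(scope="session")
def small_profiles(small_config, small_library, small_panel):
    return syn.generate_profiles(small_library, small_panel, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
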