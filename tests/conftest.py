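import numpy as np
import pytest

import methylstate as ms


@pytest.fixture(scope="session")
def config():
    return ms.SimulationConfig()


@pytest.fixture(scope="session")
def genome(config):
    return ms.generate_toy_genome(config)


@pytest.fixture(scope="session")
def reference(genome, config):
    atlas, truth = ms.generate_reference_profiles(genome, config)
    return atlas, truth


@pytest.fixture(scope="session")
def atlas(reference):
    return reference[0]


@pytest.fixture(scope="session")
def cohort(atlas, genome, config):
    """A 40-patient bulk cohort with ground truth."""
    return ms.generate_bulk_cohort(atlas, genome, config, n_samples=40)


@pytest.fixture(scope="session")
def combined_signature(atlas):
    return ms.select_signature_cpgs(atlas, mode="tiic+pbmc")


@pytest.fixture()
def rng():
    # fresh generator per test so draws do not depend on execution order
    return np.random.default_rng(20_240_917)
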