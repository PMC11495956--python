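import numpy as np
import pytest

from nectarscape import synthetic as synth


@pytest.fixture(scope="session")
def profiles():
    return synth.gen_species_pool(seed=1)


@pytest.fixture(scope="session")
def surveys(profiles):
    records, truth = synth.gen_floral_surveys(profiles, seed=1)
    return records, truth


@pytest.fixture(scope="session")
def traits(profiles):
    return synth.all_trait_table(profiles)


@pytest.fixture(scope="session")
def truth_curves(profiles):
    return {h: p.true_curve() for h, p in profiles.items()}


@pytest.fixture(scope="session")
def landscapes():
    return synth.gen_landscapes(12, seed=3)


@pytest.fixture(scope="session")
def transects():
    return synth.gen_transect_records(seed=2)


@pytest.fixture(scope="session")
def season_grid():
    return np.arange(60, 305)
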