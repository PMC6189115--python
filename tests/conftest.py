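import numpy as np
import pytest

from godwitflyway import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    """A three-year, three-site world; cheap enough for routine fits."""
    cfg = syn.SyntheticConfig(seed=11, years=tuple(range(2010, 2013)),
                              n_sites_counts=3, n_individuals=300)
    cfg.arrival.sessions_per_site_year = 40
    return cfg


@pytest.fixture(scope="session")
def small_world(small_config):
    return syn.gen_all(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
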