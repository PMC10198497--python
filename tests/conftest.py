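import numpy as np
import pytest

import mammosim as m


@pytest.fixture(scope="session")
def config():
    return m.default_config()


@pytest.fixture(scope="session")
def small_population(config):
    return m.sample_population(config, 2_000, seed=42)


@pytest.fixture
def parous_woman():
    return m.Individual(
        menarche_age=12,
        birth_ages=(25, 28),
        breastfeeds=True,
        menopause_age=50,
        death_age=85,
    )


@pytest.fixture
def nulliparous_woman():
    return m.Individual(menarche_age=12, menopause_age=50, death_age=85)


@pytest.fixture
def params():
    return m.RateParameters()


@pytest.fixture
def effects():
    return m.EffectParameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
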