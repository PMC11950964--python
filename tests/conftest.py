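import numpy as np
import pandas as pd
import pytest

from scbdeff import ScenarioConfig, generate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A quick landscape below the default study scale, for stage tests."""
    cfg = ScenarioConfig(n_sites=30, n_species=25, seed=11)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def default_landscape():
    """The default scenario: 84 plots x 67 species."""
    return generate_landscape(ScenarioConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_community(rng, n_sites, n_species, max_count=9):
    """Random integer community with no empty rows or columns."""
    while True:
        Y = rng.integers(0, max_count + 1, size=(n_sites, n_species))
        if (Y.sum(axis=1) > 0).all() and (Y.sum(axis=0) > 0).all():
            return pd.DataFrame(
                Y,
                index=[f"s{i}" for i in range(n_sites)],
                columns=[f"sp{j}" for j in range(n_species)],
            )
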