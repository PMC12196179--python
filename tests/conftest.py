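import numpy as np
import pytest

from phytonet import datasets


@pytest.fixture(scope="session")
def oil_peaks():
    return datasets.leaf_oil_peaks()


@pytest.fixture(scope="session")
def hub_table():
    return datasets.hub_centralities()


@pytest.fixture(scope="session")
def degree_scores():
    return datasets.compound_degree_scores()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
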