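import numpy as np
import pytest

from eibm import synthcohort


@pytest.fixture(scope="session")
def parc16():
    return synthcohort.make_geometry(16, n_communities=3, seed=11)


@pytest.fixture(scope="session")
def parc68():
    return synthcohort.make_geometry(68, n_communities=4, seed=12)


@pytest.fixture(scope="session")
def conn68(parc68):
    return synthcohort.make_connectome(parc68, density=0.3, seed=13)


@pytest.fixture(scope="session")
def maps68(parc68):
    return synthcohort.make_annotation_maps(parc68, smoothness=5.0, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
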