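import numpy as np
import pytest

from mscmig.demography import (DemographicModel, MigrationBand,
                               PopulationTree)
from mscmig.coalsim import SampleConfig


@pytest.fixture(scope="session")
def single_pop_model():
    """One population of scaled size 0.001 (degenerate tree)."""
    return DemographicModel(PopulationTree({}, {}, {"X": 0.001}))


@pytest.fixture(scope="session")
def two_pop_model():
    """(A,B) split at tau=0.001; theta 0.001/0.001/0.002."""
    tree = PopulationTree({"A": "root", "B": "root"}, {"root": 0.001},
                          {"A": 0.001, "B": 0.001, "root": 0.002})
    return DemographicModel(tree)


@pytest.fixture(scope="session")
def two_pop_band_model():
    """Two populations with a forward-time A->B band (M=200)."""
    tree = PopulationTree({"A": "root", "B": "root"}, {"root": 0.001},
                          {"A": 0.001, "B": 0.001, "root": 0.002})
    return DemographicModel(tree, [MigrationBand("A", "B", 200.0)])


@pytest.fixture(scope="session")
def pair_samples():
    return SampleConfig({"A": 1, "B": 1})


@pytest.fixture(scope="session")
def quartet_samples():
    return SampleConfig({"A": 2, "B": 2})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
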