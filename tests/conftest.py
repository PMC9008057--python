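import numpy as np
import pytest

from hhscan.io import GroupMap
from hhscan.network import MutationModel, SampleDesign, SpeciesNetwork


@pytest.fixture
def one_per_group_design() -> SampleDesign:
    return SampleDesign({"C": 1, "D": 1, "O": 1, "A": 1})


@pytest.fixture
def small_design() -> SampleDesign:
    return SampleDesign.from_individuals(2, 2, 2, 1)


@pytest.fixture
def tree_network() -> SpeciesNetwork:
    """Gamma-free network with internal branch T = 1."""
    return SpeciesNetwork(t_h=5.0, t_co=6.0, t_root=9.0, gamma=0.0)


@pytest.fixture
def hybrid_network() -> SpeciesNetwork:
    return SpeciesNetwork(t_h=2.0, t_co=2.5, t_root=5.0, gamma=0.3)


@pytest.fixture
def indel_model() -> MutationModel:
    return MutationModel(theta=1.0, indel_fraction=1.0)


@pytest.fixture
def single_tip_groups() -> GroupMap:
    return GroupMap({"C1": "C", "D1": "D", "O1": "O", "A1": "A"})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
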