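import numpy as np
import pytest

from torsiongen import molio, molgraph
from torsiongen.molio import Conformation


@pytest.fixture(scope="session")
def butane():
    """United-atom 4-carbon chain: one rotatable dihedral."""
    return molio.make_fixture("chain", 4, seed=1)


@pytest.fixture(scope="session")
def butane_topo(butane):
    return molgraph.prepare_rotamer_metadata(butane)


@pytest.fixture(scope="session")
def polyala():
    """3-residue backbone-only polyalanine."""
    return molio.make_fixture("polyala", 3, seed=2)


@pytest.fixture(scope="session")
def polyala_topo(polyala):
    return molgraph.prepare_rotamer_metadata(polyala)


@pytest.fixture(scope="session")
def all_fixtures():
    return {
        "chain": molio.make_fixture("chain", 6, seed=3),
        "ring": molio.make_fixture("ring", 6, seed=4),
        "branched": molio.make_fixture("branched", 6, seed=5),
        "polyala": molio.make_fixture("polyala", 3, seed=6),
    }


def conf_of(system) -> Conformation:
    return Conformation(system.positions())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
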