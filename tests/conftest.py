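import numpy as np
import pytest
from rdkit import Chem, RDLogger

from monopka.fixtures import FixtureSpec, generate_curation_fixture

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def curation_fixture(tmp_path_factory):
    """Default 40-record curation fixture with its expected-fate manifest."""
    path = tmp_path_factory.mktemp("fixture") / "curation.sdf"
    return generate_curation_fixture(FixtureSpec(seed=11), path)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def mol():
    def _make(smiles):
        m = Chem.MolFromSmiles(smiles)
        assert m is not None, f"test SMILES failed to parse: {smiles}"
        return m
    return _make
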