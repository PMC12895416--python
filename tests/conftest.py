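import numpy as np
import pytest

from mdcompress.synthetic import alanine_dipeptide_pdb, polyalanine_pdb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def polyala39_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "polyala39.pdb"
    polyalanine_pdb(39, path)
    return path


@pytest.fixture(scope="session")
def polyala35_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "polyala35.pdb"
    polyalanine_pdb(35, path)
    return path


@pytest.fixture(scope="session")
def dipeptide_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "ala2.pdb"
    alanine_dipeptide_pdb(path)
    return path
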