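import pytest

from linksmith import fixtures


@pytest.fixture(scope="session")
def table():
    return fixtures.builtin_parameter_table()


@pytest.fixture(scope="session")
def library():
    return fixtures.builtin_fragments()


@pytest.fixture()
def gly(library):
    return library.monomers["GLY"].copy()


@pytest.fixture()
def ala(library):
    return library.monomers["ALA"].copy()


@pytest.fixture()
def lys(library):
    return library.monomers["LYS"].copy()


@pytest.fixture()
def plp(library):
    return library.monomers["PLP"].copy()


@pytest.fixture()
def glc(library):
    return library.monomers["GLC"].copy()
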