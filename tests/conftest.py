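import pytest

from slimnet import datafiles
from slimnet.records import ProteinRecord


@pytest.fixture(scope="session")
def patterns():
    return datafiles.packaged_patterns()


@pytest.fixture(scope="session")
def patterns_by_id(patterns):
    return {p.motif_id: p for p in patterns}


@pytest.fixture(scope="session")
def interactors():
    return datafiles.packaged_interactions()


@pytest.fixture(scope="session")
def placements():
    return datafiles.packaged_placements()


@pytest.fixture(scope="session")
def inventory():
    return datafiles.packaged_site_inventory()


@pytest.fixture(scope="session")
def compatibility():
    return datafiles.packaged_compatibility()


@pytest.fixture
def toy_protein():
    return ProteinRecord(accession="TOY", name="toy", sequence="MKTESLV")


def make_protein(sequence: str, accession: str = "P1") -> ProteinRecord:
    return ProteinRecord(accession=accession, name=accession, sequence=sequence)
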