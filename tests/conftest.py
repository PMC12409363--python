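import pytest

from aribseq.reference import (load_packaged_modifications,
                               load_packaged_references)

HOST_IDS = ("Eco-Asn-GUU", "Eco-Lys-UUU", "Eco-Thr-CGU", "Eco-Thr-UGU")


@pytest.fixture(scope="session")
def host_records():
    return load_packaged_references(include_phage=False)


@pytest.fixture(scope="session")
def all_records():
    return load_packaged_references(include_phage=True)


@pytest.fixture(scope="session")
def by_id(all_records):
    return {r.id: r for r in all_records}


@pytest.fixture(scope="session")
def lys(by_id):
    return by_id["Eco-Lys-UUU"]


@pytest.fixture(scope="session")
def mods():
    return load_packaged_modifications()
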