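import pytest

from cyclodisplay import LibraryDesign, make_codon_table

PADI4_3_CORE = "RDHHYRHPKY"          # random region of the lead inhibitor
PADI4_3_SYNTH = "YRDHHYRHPKYCG"      # its 13-residue synthesis form


@pytest.fixture(scope="session")
def design():
    return LibraryDesign()


@pytest.fixture(scope="session")
def table_d():
    return make_codon_table("main_D")


@pytest.fixture(scope="session")
def table_scan():
    return make_codon_table("scanning")
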