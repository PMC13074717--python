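import pytest

import haplokit as hk


@pytest.fixture(scope="session")
def fixture_aln():
    aln, _ = hk.anafp_fixture()
    return aln


@pytest.fixture(scope="session")
def fixture_popmap():
    _, popmap = hk.anafp_fixture()
    return popmap


@pytest.fixture(scope="session")
def fixture_sites(fixture_aln):
    return hk.detect_variable_sites(fixture_aln)


@pytest.fixture(scope="session")
def fixture_table(fixture_aln, fixture_sites):
    return hk.assign_haplotypes(fixture_aln, fixture_sites)
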