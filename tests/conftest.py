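import pytest

from inpp5d_iso import (build_toy_catalog, haplotype_frequencies,
                        load_paper_fixture, parse_allele_kmer,
                        RS1141328_KMER_SPEC)


@pytest.fixture(scope="session")
def catalog():
    return build_toy_catalog()


@pytest.fixture(scope="session")
def kmer_pair():
    return parse_allele_kmer(RS1141328_KMER_SPEC)


@pytest.fixture(scope="session")
def hap_model():
    return haplotype_frequencies(0.498, 0.220, 0.18)


@pytest.fixture(scope="session")
def fixture_tables():
    return load_paper_fixture()
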