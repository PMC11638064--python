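import pytest

from branchretain import synthetic_data as syn
from branchretain.gene_model import build_region_set


@pytest.fixture(scope="session")
def locus():
    """Default minus-strand gene + pseudogene locus."""
    return syn.build_paralog_pair(seed=0)


@pytest.fixture(scope="session")
def regions(locus):
    call = locus.splice_call()
    return build_region_set(locus.gene, call.retained_len)


@pytest.fixture(scope="session")
def plus_locus():
    """Plus-strand mirror of the default locus for strand-invariance checks."""
    return syn.build_paralog_pair(seed=0, strand="+")
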