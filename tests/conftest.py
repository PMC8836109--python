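import pytest

from famprio import FilterConfig, SegregationPolicy, assign_roles
from famprio.datasets import crc_candidate_variants, crc_family_pedigree


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def policy():
    return SegregationPolicy()


@pytest.fixture
def family():
    return assign_roles(crc_family_pedigree())


@pytest.fixture
def candidates():
    return crc_candidate_variants()


@pytest.fixture
def by_gene(candidates):
    return {r.gene: r for r in candidates.records}
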