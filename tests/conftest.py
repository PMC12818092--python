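import numpy as np
import pytest

from crataegus.genotypes import Genotype, Locus


@pytest.fixture(scope="session")
def dinucleotide_locus():
    return Locus("locA", 2)


@pytest.fixture
def unit_loci():
    """Loci with motif length 1, so allele sizes equal repeat counts."""
    return {"a": Locus("a", 1), "b": Locus("b", 1)}


def make_genotype(ind, alleles, ploidy=2, pop="pop1", taxon=None):
    return Genotype(ind, pop, ploidy, alleles, taxon_label=taxon)


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20250928)
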