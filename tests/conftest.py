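import numpy as np
import pytest

from ibdnet.genmap import make_genetic_map
from ibdnet.pedigree import drop_haplotypes, simulate_pedigree


@pytest.fixture(scope="session")
def gmap():
    return make_genetic_map()


@pytest.fixture(scope="session")
def small_map():
    # four 100 cM chromosomes: fast, still multi-chromosome
    return make_genetic_map([100.0, 100.0, 100.0, 100.0])


@pytest.fixture(scope="session")
def nuclear(gmap):
    """One couple with two children, plus dropped haplotypes."""
    ped = simulate_pedigree(n_families=1, generations=2, children_per_couple=2, seed=11)
    haps = drop_haplotypes(ped, gmap, seed=12)
    return ped, haps


@pytest.fixture(scope="session")
def cousin_pedigree():
    """Three generations of one family: grandparents, two sib couples, cousins."""
    return simulate_pedigree(n_families=1, generations=3, children_per_couple=2, seed=5)
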