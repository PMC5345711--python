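import numpy as np
import pytest

from mtqtl import (GeneticMap, GenotypeMatrix, PhenotypeMatrix,
                   simulate_ril_genotypes, simulate_traits)
from mtqtl.simulate import QTLEffectSpec, desk_map, exchangeable_sigma


@pytest.fixture(scope="session")
def tiny_map() -> GeneticMap:
    return GeneticMap(("m1", "m2", "m3", "m4"), ("chr1", "chr1", "chr2", "chr2"),
                      np.array([0.0, 8.0, 0.0, 12.0]))


@pytest.fixture(scope="session")
def small_data(tiny_map):
    """N=40, p=3 data with one real effect at m2: (geno, pheno, spec)."""
    geno = simulate_ril_genotypes(tiny_map, 40, seed=3)
    sigma = exchangeable_sigma(3, 0.5)
    gamma = np.zeros((1, 3))
    gamma[0, 1] = 0.9
    spec = QTLEffectSpec(np.zeros(3), ("m2",), gamma, sigma)
    pheno = simulate_traits(geno, spec, seed=4)
    return geno, pheno, spec


@pytest.fixture(scope="session")
def null_data(tiny_map):
    """N=40, p=3 data with no QTL anywhere."""
    geno = simulate_ril_genotypes(tiny_map, 40, seed=5)
    spec = QTLEffectSpec(np.zeros(3), (), np.zeros((0, 3)),
                         exchangeable_sigma(3, 0.5))
    pheno = simulate_traits(geno, spec, seed=6)
    return geno, pheno


@pytest.fixture(scope="session")
def desk_map_fixture() -> GeneticMap:
    return desk_map()
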