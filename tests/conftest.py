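import numpy as np
import pytest

from automixia import simgenome as sg


@pytest.fixture(scope="session")
def small_genome() -> sg.GenomeMap:
    """Two small chromosomes, one acrocentric and one metacentric."""
    return sg.GenomeMap(
        (
            sg.Chromosome("chr1", 1_000_000, 100_000),
            sg.Chromosome("chr2", 800_000, 400_000),
        )
    )


@pytest.fixture(scope="session")
def mother(small_genome) -> sg.MaternalGenotype:
    return sg.simulate_maternal_genome(
        small_genome, het_density=2e-3, hom_density=1e-3, seed=101
    )


@pytest.fixture(scope="session")
def father(mother) -> sg.MaternalGenotype:
    return sg.derive_paternal_genome(mother)


@pytest.fixture(scope="session")
def one_chrom_genome() -> sg.GenomeMap:
    return sg.GenomeMap((sg.Chromosome("chr1", 1_000_000, 100_000),))


@pytest.fixture(scope="session")
def probe_sites_mother(one_chrom_genome) -> sg.MaternalGenotype:
    """Heterozygous probe sites at known distances from the centromere."""
    pos = np.array([50_000, 300_000, 600_000, 950_000], dtype=np.int64)
    block = sg.SiteBlock(pos, np.zeros(4, np.uint8), np.ones(4, np.uint8))
    return sg.MaternalGenotype(one_chrom_genome, {"chr1": block})
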