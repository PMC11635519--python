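import pytest

from secretile import (
    CloningConfig,
    TileParams,
    design_oligos,
    random_proteome,
    tile_proteome,
)

# arms chosen free of BsrGI/PstI sites on both strands (validated at load)
ARM5 = "ACGGCTAGCAAGGAGATATACAT"
ARM3 = "TGAGCGGCCGCTTCGAGCAGAC"


@pytest.fixture(scope="session")
def cloning():
    return CloningConfig(five_prime_arm=ARM5, three_prime_arm=ARM3, seed=7)


@pytest.fixture(scope="session")
def proteome_small():
    return random_proteome(n_proteins=10, length=200, seed=11)


@pytest.fixture(scope="session")
def library_small(proteome_small):
    return tile_proteome(proteome_small, TileParams())


@pytest.fixture(scope="session")
def designs_small(library_small, cloning):
    return design_oligos(library_small, cloning)
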