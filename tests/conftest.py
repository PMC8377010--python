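import numpy as np
import pytest

from sgrescue import simulate_reference


@pytest.fixture(scope="session")
def sim_genome_cds():
    """A small two-chromosome reference embedding a 738-nt CDS (protein
    length 245), shared across tests that need realistic coordinates."""
    return simulate_reference(
        7,
        {"chr20s": 4000, "chr16s": 3000},
        {"name": "EIF6s", "chrom": "chr20s", "start": 1501, "n_coding_nt": 738},
    )


@pytest.fixture(scope="session")
def sim_genome(sim_genome_cds):
    return sim_genome_cds[0]


@pytest.fixture(scope="session")
def sim_cds(sim_genome_cds):
    return sim_genome_cds[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cds_seq(rng: np.random.Generator, n_codons: int) -> str:
    """A random valid CDS string: ATG, non-stop middle codons, one stop."""
    stops = ["TAA", "TAG", "TGA"]
    codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in stops
    ]
    mid = rng.choice(codons, size=max(0, n_codons - 2))
    return "ATG" + "".join(mid) + stops[rng.integers(0, 3)]
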