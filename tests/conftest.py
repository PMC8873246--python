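import numpy as np
import pytest

from regulocus import SimConfig, digest
from regulocus.intervals import GenomicInterval
from regulocus.simulate import fragment_map_for, make_genome, make_locus


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact locus: fast to simulate, same structure as the default."""
    return SimConfig(
        genome_length=400_000,
        tad_boundaries=(80_000, 150_000, 300_000),
        se_interval=GenomicInterval("chrS", 160_000, 202_000),
        n_genes=2,
        n_nuclei_per_class=(20, 30),
        read_depth=100_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_locus(small_config):
    return make_locus(small_config)


@pytest.fixture(scope="session")
def small_genome(small_config):
    sequence, positions = make_genome(small_config)
    return sequence, positions


@pytest.fixture(scope="session")
def small_fragmap(small_config, small_genome):
    _, positions = small_genome
    return fragment_map_for(small_config, positions)


@pytest.fixture()
def toy_map():
    """Fragment map of a hand-checkable 30 bp contig."""
    #            0123456789...
    sequence = "TTGATCAAAAGATCAAAAAGATCAAAAAAA"
    return digest(sequence, "GATC", chrom="chrT"), sequence
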