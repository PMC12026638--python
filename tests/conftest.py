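import numpy as np
import pytest

from bsjnet.genome_io import Genome, GenomicInterval, build_dataset
from bsjnet.synthetic_data import SyntheticSpec, simulate_dataset

BASES = "ACGT"


@pytest.fixture(scope="session")
def toy_chromosome() -> str:
    rng = np.random.default_rng(123)
    return "".join(rng.choice(list(BASES), size=300))


@pytest.fixture(scope="session")
def toy_genome(toy_chromosome) -> Genome:
    return Genome({"chr1": toy_chromosome})


@pytest.fixture(scope="session")
def small_synthetic():
    """40-record planted-motif bundle shared across tests (session cached)."""
    spec = SyntheticSpec(n_pos=20, n_neg=20, n_chromosomes=2, chrom_length=30_000, seed=5)
    genome, pos, neg, manifest = simulate_dataset(spec)
    return spec, genome, pos, neg, manifest


@pytest.fixture(scope="session")
def small_dataset(small_synthetic):
    spec, genome, pos, neg, _ = small_synthetic
    return build_dataset(pos, neg, genome, spec.flank_len)
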