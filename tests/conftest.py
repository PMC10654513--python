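import numpy as np
import pytest

from peakamp.genome import Genome, GenomicInterval, IntervalSet
from peakamp.synth import GenerativeParams, simulate_dataset


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return Genome({"chr1": 400_000, "chr2": 400_000})


@pytest.fixture(scope="session")
def small_sim(toy_genome):
    """One shared desk-scale simulation exercising all assays."""
    params = GenerativeParams(
        n_sites=150, n_genes=10, gene_min_len=5_000, gene_max_len=20_000,
        n_dtres=10, n_enhancers=10, n_blacklist=3, seed=7,
    )
    return simulate_dataset(params, genome=toy_genome, make_sequences=True)


def random_interval_set(
    rng: np.random.Generator, genome: Genome, n: int, max_len: int = 500,
    name: str = "",
) -> IntervalSet:
    chroms = list(genome)
    out = []
    for _ in range(n):
        chrom, L = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, L - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out, name=name)
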