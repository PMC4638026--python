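import numpy as np
import pytest

from hvdi import (
    analyze_virome,
    assemble,
    construct_abundance_profile,
    generate_genome_pool,
    sample_reads,
)
from hvdi._seq import revcomp


@pytest.fixture(scope="session")
def small_pool():
    """Five well-separated 10-kb random genomes."""
    return generate_genome_pool(5, (10_000, 10_000), gc_content=0.455, seed=11)


@pytest.fixture(scope="session")
def uniform_virome(small_pool):
    """Error-free reads at ~20x coverage from the 5-genome pool."""
    profile = construct_abundance_profile(5, 1.0, genotype_ids=small_pool.ids)
    return sample_reads(small_pool, profile, 5000, seed=21)


@pytest.fixture(scope="session")
def uniform_analysis(uniform_virome):
    """The uniform virome pushed through QC, assembly and clustering."""
    return analyze_virome(uniform_virome)


@pytest.fixture(scope="session")
def tiled_reads(small_pool):
    """Error-free 200-nt reads tiled every 50 nt across genome 1,
    alternating strands: assembles into exactly the source genome."""
    g = small_pool[0]
    reads = []
    for idx, start in enumerate(range(0, g.length - 200 + 1, 50)):
        seq = g.sequence[start : start + 200]
        if idx % 2:
            seq = revcomp(seq)
        reads.append((f"tile_{idx + 1:05d}", seq))
    return g, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
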