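import numpy as np
import pytest

from syntenon.formats import Chromosome, Gene, Genome, GenomeCollection
from syntenon.simulate import SimulationConfig, simulate_genomes


def make_genome(gid, cogs, strands=None, spacing=1100, gene_len=1000,
                length=None, circular=True):
    """A single-chromosome genome from a COG-label sequence ('.' = no COG)."""
    n = len(cogs)
    clen = length or n * spacing
    genes = []
    for i, c in enumerate(cogs):
        strand = strands[i] if strands else "+"
        genes.append(Gene(f"{gid}_{i:03d}", "chr", i * spacing,
                          i * spacing + gene_len, strand,
                          None if c == "." else c))
    return Genome(gid, [Chromosome("chr", clen, circular)], genes)


@pytest.fixture(scope="session")
def small_sim():
    """A small evolved collection with planted clusters, shared across tests."""
    cfg = SimulationConfig(seed=1, n_genomes=12, n_cogs=400,
                           planted_clusters=[(5, 1.0)] * 6)
    collection, truth = simulate_genomes(cfg)
    return cfg, collection, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
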