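import numpy as np
import pytest

from metaepi.io import Genome, Kingdom
from metaepi.synth import SynthConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A scaled-down corpus: quick to generate, still structured."""
    return SynthConfig(
        seed=42,
        genome_length=30_000,
        genes_per_strand=12,
        mean_gene_length=600,
        n_samples=4,
        depth_per_strand=60.0,
        n_loci=300,
        phage_per_clade=5,
        phage_length=8_000,
    )


@pytest.fixture(scope="session")
def small_corpus(small_config):
    genome, genes, truth = simulate_genome(small_config)
    return {"genome": genome, "genes": genes, "truth": truth, "config": small_config}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_genome(seq: str, name: str = "g", contig: str = "c1",
                kingdom: Kingdom = Kingdom.prokaryote) -> Genome:
    return Genome(name, [(contig, seq)], kingdom)
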