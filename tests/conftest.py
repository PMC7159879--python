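import numpy as np
import pytest

from conflictscan.model import DomainHit, GeneRecord, GenomeRecord
from conflictscan.simulate import SimConfig, generate


def make_gene(gene_id, start, end, strand="+", genome="G1", replicon="chr",
              protein=None):
    return GeneRecord(
        gene_id=gene_id,
        protein_id=protein or gene_id + "_p",
        genome_id=genome,
        replicon_id=replicon,
        start=start,
        end=end,
        strand=strand,
    )


def make_genome(genes, genome_id="G1", replicon="chr", length=100_000,
                phylum="Actinobacteria", multicellular="True"):
    return GenomeRecord(
        genome_id=genome_id,
        phylum=phylum,
        multicellular=multicellular,
        replicons={replicon: length},
        genes=list(genes),
    )


def hit(protein, domain, start, end, score=100.0):
    return DomainHit(protein, domain, start, end, score, 1e-10)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared across read-only tests."""
    return generate(SimConfig(seed=42, n_genomes=60, genes_per_genome=40))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
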