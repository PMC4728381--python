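import io

import pytest
from hypothesis import settings

import hmcpeaks as h

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def sim_genome():
    """Default 1-Mb synthetic genome (5 x 200 kb, 60 genes)."""
    genes, contigs = h.simulate_genome_models(h.GenomeSpec(seed=1))
    return genes, contigs


@pytest.fixture(scope="session")
def sim_element_map(sim_genome):
    genes, contigs = sim_genome
    return h.build_element_map(genes, contigs)


@pytest.fixture(scope="session")
def sim_peaks(sim_genome):
    genes, contigs = sim_genome
    bed = h.simulate_peaks(genes, contigs, h.PeakSpec(n_peaks=5000, seed=2))
    return h.read_bed_peaks(io.StringIO(bed))


def make_gene(gene_id="g1", contig="ctg1", body=(0, 300),
              exons=((0, 100), (200, 300)), strand="+"):
    return h.GeneModel(
        gene_id,
        h.GenomicInterval(contig, body[0], body[1], strand),
        tuple(h.GenomicInterval(contig, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def gene_factory():
    return make_gene
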