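import numpy as np
import pytest

from lncevo.gene_models import GeneModel, TranscriptModel
from lncevo.intervals import GenomicInterval
from lncevo.synthetic import SimulationConfig, simulate_genomes


def make_gene(gid, exon_coords, chrom="chr1", strand="+", biotype="lincRNA",
              source="novel", gene_class="other", n_tx=1):
    """Gene with one transcript per exon list (exon_coords: list of (s, e)
    or list of such lists for multiple isoforms)."""
    if exon_coords and isinstance(exon_coords[0], tuple):
        exon_coords = [exon_coords]
    txs = [
        TranscriptModel(
            f"{gid}.t{i+1}", gid,
            [GenomicInterval(chrom, s, e, strand) for s, e in coords],
            biotype=biotype,
        )
        for i, coords in enumerate(exon_coords)
    ]
    return GeneModel(gid, txs, biotype=biotype, gene_class=gene_class, source=source)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def genomes(default_config):
    """The default synthetic two-species fixture (built once per session)."""
    return simulate_genomes(default_config)


@pytest.fixture(scope="session")
def orthology_result(genomes):
    from lncevo.pipeline import run_orthology

    return run_orthology(genomes)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
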