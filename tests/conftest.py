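import numpy as np
import pytest

from splicecis.gene_models import extract_internal_exon_features
from splicecis.synthetic_data import (SimulationConfig, default_ese_set,
                                      simulate_ortholog_pair,
                                      simulate_species_genes)


@pytest.fixture(scope="session")
def motifs():
    return default_ese_set("int3")


@pytest.fixture(scope="session")
def small_gene_set(motifs):
    """~60 genes with planted ESEs plus the genome they live on."""
    cfg = SimulationConfig(seed=20, n_genes=60)
    genes, genome = simulate_species_genes(cfg, motifs)
    return genes, genome


@pytest.fixture(scope="session")
def small_bundle_paths(small_gene_set, tmp_path_factory):
    """The small gene set written to GFF3 + FASTA on disk."""
    from splicecis.gene_models import write_gff3

    genes, genome = small_gene_set
    d = tmp_path_factory.mktemp("bundle")
    gff = d / "annotation.gff3"
    fasta = d / "genome.fasta"
    write_gff3(genes, str(gff))
    with open(fasta, "w") as fh:
        for sid, seq in genome.items():
            fh.write(f">{sid}\n{seq}\n")
    return str(gff), str(fasta)


@pytest.fixture(scope="session")
def aligned_features(small_gene_set, motifs):
    """Ortholog alignments for the small gene set at planted c = 0.5."""
    from splicecis.ese_constraint import align_gene_features

    genes, _ = small_gene_set
    rng = np.random.default_rng(99)
    afs = []
    for g in genes:
        a, b = simulate_ortholog_pair(g, motifs, d_core=0.06, c=0.5,
                                      seed=int(rng.integers(2 ** 31)))
        afs += align_gene_features(g, extract_internal_exon_features(g), a, b)
    return afs
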