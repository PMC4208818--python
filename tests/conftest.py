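import pytest

from iqdfam.io import extract_cds, translate_cds
from iqdfam.simulate import FamilySpec, generate_family_genome


@pytest.fixture(scope="session")
def family():
    """A small synthetic family genome shared across tests.

    Defaults: 8 IQD genes (1 tandem pair, 2 segmental blocks, 2 singles),
    40 background genes on 4 chromosomes, Ka/Ks targets 0.03/0.12.
    """
    genome, annotation, truth = generate_family_genome(FamilySpec(seed=1))
    return genome, annotation, truth


@pytest.fixture(scope="session")
def family_sequences(family):
    """CDS and protein per gene, derived from the genome via extraction."""
    genome, annotation, _ = family
    chroms = {r.id: r for r in genome}
    cds = {
        g.gene_id: extract_cds(g, chroms[g.chromosome]) for g in annotation.genes
    }
    proteins = {gid: translate_cds(c) for gid, c in cds.items()}
    return cds, proteins
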