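import pytest

from vgsckit.fixture import paper_fixture
from vgsckit.gene_model import GeneModel
from vgsckit.topology import annotate_topology
from vgsckit.variants import annotate_all


@pytest.fixture(scope="session")
def bundle():
    """The packaged study fixture (gene, topology, catalog, 37 variants)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def annotated(bundle):
    """The 37 fixture variants, fully annotated (class + topology + matches)."""
    effects = annotate_all(bundle.gene_model, bundle.observations)
    return annotate_topology(
        effects, bundle.topology, bundle.canonical_map, bundle.catalog
    )


@pytest.fixture()
def toy_gene():
    """Tiny two-exon gene: CDS 'ATGGTTCCTAAG' (M V P K), no stop on purpose."""
    return GeneModel("toy", "AAATGGTTTCCTAAGG", ((3, 8), (10, 15)))
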