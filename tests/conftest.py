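import pytest

from biofilmtraits import default_rulebook
from biofilmtraits.io import GenomeAnnotation


@pytest.fixture(scope="session")
def rulebook():
    return default_rulebook()


def make_annotation(genome_id="g", genes=(), ecs=(), products=()):
    return GenomeAnnotation(
        genome_id=genome_id, genes=set(genes), ecs=set(ecs), products=set(products)
    )


@pytest.fixture
def annotation_factory():
    return make_annotation
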