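import hypothesis
import pytest

from phenomatch.corpus import AnnotationCorpus
from phenomatch.ontology import Ontology, TermNode

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("det")


# nine-term toy hierarchy:
#   R -> A, B;  A -> A1, A2;  B -> B1;  A1 -> A1a, A1b;  B1 -> B1a
TOY_PARENTS: dict[str, set[str]] = {
    "R": set(),
    "A": {"R"},
    "B": {"R"},
    "A1": {"A"},
    "A2": {"A"},
    "B1": {"B"},
    "A1a": {"A1"},
    "A1b": {"A1"},
    "B1a": {"B1"},
}


def make_ontology(parents: dict[str, set[str]]) -> Ontology:
    return Ontology(
        TermNode(term_id=t, parent_ids=frozenset(ps)) for t, ps in parents.items()
    )


@pytest.fixture(scope="session")
def toy_ontology() -> Ontology:
    return make_ontology(TOY_PARENTS)


TOY_DRUG_ANN: dict[str, set[str]] = {
    "D1": {"A1a", "A1b"},
    "D2": {"A1a", "B1a"},
    "D3": {"A2", "B1a"},
    "D4": {"A1b", "A2", "B1a"},
}

TOY_GENE_ANN: dict[str, set[str]] = {
    "G1": {"A1a", "A1b"},
    "G2": {"B1a", "A2"},
    "G3": {"A1a", "A2", "B1a"},
}


@pytest.fixture(scope="session")
def toy_drug_corpus() -> AnnotationCorpus:
    return AnnotationCorpus(TOY_DRUG_ANN, entity_class="drug")


@pytest.fixture(scope="session")
def toy_gene_corpus() -> AnnotationCorpus:
    return AnnotationCorpus(TOY_GENE_ANN, entity_class="gene")
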