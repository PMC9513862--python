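import pytest

from fundusnlp import SynthConfig, generate_corpus
from fundusnlp.schema import AnnotatedDocument, Category, ConceptMention, RelationInstance


def mention(mid, cat, start, end, text, negated=False):
    return ConceptMention(
        id=mid, category=cat, start=start, end=end, surface=text[start:end], negated=negated
    )


@pytest.fixture(scope="session")
def small_corpus():
    """200 synthetic documents, fixed seed, shared across tests."""
    return generate_corpus(SynthConfig(n_docs=200, seed=1))


@pytest.fixture()
def simple_doc():
    """One hand-built document exercising every annotation type."""
    text = "no exudate but mild hemorrhage in the macula of the right eye."
    mentions = [
        mention("T1", Category.LESION, 3, 10, text, negated=True),      # exudate
        mention("T2", Category.SEVERITY, 15, 19, text),                 # mild
        mention("T3", Category.LESION, 20, 30, text),                   # hemorrhage
        mention("T4", Category.EYE_PART, 38, 44, text),                 # macula
        mention("T5", Category.LATERALITY, 52, 61, text),               # right eye
    ]
    from fundusnlp.schema import RelationType

    relations = [
        RelationInstance("R1", RelationType.SEVERITY_LESION, "T2", "T3"),
        RelationInstance("R2", RelationType.LOCATED, "T4", "T3"),
        RelationInstance("R3", RelationType.LATERALITY_LESION, "T5", "T3"),
    ]
    doc = AnnotatedDocument("simple", text, mentions, relations)
    doc.validate()
    return doc
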