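import pytest

from fundusnlp import (
    extract_relations,
    featurize,
    generate_candidates,
    train_relation_classifier,
)
from fundusnlp.relation import ClassifierError, RelationClassifier
from fundusnlp.schema import (
    RELATION_FOR_ATTRIBUTE,
    AnnotatedDocument,
    Category,
    ConceptMention,
    RelationType,
)
from fundusnlp.textproc import sentence_of, split_sentences


def _doc(text, spans):
    """spans: list of (category, start, end)."""
    mentions = [
        ConceptMention(f"T{i+1}", cat, s, e, text[s:e])
        for i, (cat, s, e) in enumerate(spans)
    ]
    return AnnotatedDocument("d", text, mentions)


class TestGenerateCandidates:
    def test_lesion_and_severity_pair(self):
        doc = _doc("mild hemorrhage", [(Category.SEVERITY, 0, 4), (Category.LESION, 5, 15)])
        (pair,) = generate_candidates(doc)
        assert pair.implied_type is RelationType.SEVERITY_LESION
        assert pair.label == "negative"  # no gold relation present

    def test_severity_and_eye_part_never_paired(self):
        doc = _doc("mild macula", [(Category.SEVERITY, 0, 4), (Category.EYE_PART, 5, 11)])
        assert generate_candidates(doc) == []

    def test_cross_sentence_never_paired(self):
        doc = _doc(
            "hemorrhage. right eye",
            [(Category.LESION, 0, 10), (Category.LATERALITY, 12, 21)],
        )
        assert generate_candidates(doc) == []

    def test_two_lesions_two_attributes_give_four(self):
        text = "mild hemorrhage and exudate of the right eye"
        doc = _doc(
            text,
            [
                (Category.SEVERITY, 0, 4),
                (Category.LESION, 5, 15),
                (Category.LESION, 20, 27),
                (Category.LATERALITY, 35, 44),
            ],
        )
        pairs = generate_candidates(doc)
        assert len(pairs) == 4
        got = {(p.lesion.surface, p.attribute.surface) for p in pairs}
        assert got == {
            ("hemorrhage", "mild"),
            ("hemorrhage", "right eye"),
            ("exudate", "mild"),
            ("exudate", "right eye"),
        }

    def test_equals_brute_force_enumeration(self, small_corpus):
        """Candidate generation = double loop over mentions filtered by the
        same-sentence + schema predicate, on 100 synthetic documents."""
        for doc in small_corpus[:100]:
            sentences = split_sentences(doc.text)
            expected = set()
            for lesion in doc.mentions:
                if lesion.category is not Category.LESION:
                    continue
                for attr in doc.mentions:
                    if attr.category is Category.LESION:
                        continue
                    s1 = sentence_of(sentences, lesion)
                    s2 = sentence_of(sentences, attr)
                    if s1 is not None and s1 is s2:
                        expected.add((lesion.id, attr.id, RELATION_FOR_ATTRIBUTE[attr.category]))
            got = {
                (p.lesion.id, p.attribute.id, p.implied_type)
                for p in generate_candidates(doc)
            }
            assert got == expected

    def test_gold_labels(self, simple_doc):
        pairs = generate_candidates(simple_doc)
        labels = {(p.attribute.id, p.lesion.id): p.label for p in pairs}
        # all three attributes link to T3, none to the negated T1
        assert labels[("T2", "T3")] == "positive"
        assert labels[("T4", "T3")] == "positive"
        assert labels[("T5", "T3")] == "positive"
        assert labels[("T2", "T1")] == "negative"


class TestFeaturize:
    def test_deterministic(self, simple_doc):
        a, b = generate_candidates(simple_doc), generate_candidates(simple_doc)
        assert [featurize(p) for p in a] == [featurize(p) for p in b]

    def test_swapping_lesion_changes_representation(self, simple_doc):
        pairs = {(p.attribute.id, p.lesion.id): p for p in generate_candidates(simple_doc)}
        assert featurize(pairs[("T2", "T1")]) != featurize(pairs[("T2", "T3")])

    def test_adjacent_mentions_distance_one(self):
        doc = _doc("mild hemorrhage", [(Category.SEVERITY, 0, 4), (Category.LESION, 5, 15)])
        (pair,) = generate_candidates(doc)
        assert abs(featurize(pair)["dist"]) == 1.0


@pytest.fixture(scope="module")
def classifier(small_corpus):
    pairs = [p for d in small_corpus for p in generate_candidates(d)]
    return train_relation_classifier(pairs, seed=2), pairs


class TestTrainClassifier:
    def test_training_f1_near_perfect(self, small_corpus, classifier):
        """Templated pairs are separable; training-set F1 must be >= 0.99."""
        from fundusnlp import evaluate_relations
        from fundusnlp.pipeline import run_gold_setting

        clf, _ = classifier
        preds = run_gold_setting(small_corpus, clf)
        report = evaluate_relations(preds, small_corpus, setting="gold")
        assert report.micro.strict.f1 >= 0.99

    def test_deterministic_given_seed(self, classifier):
        clf, pairs = classifier
        again = train_relation_classifier(pairs, seed=2)
        assert clf.decide(pairs[:200]) == again.decide(pairs[:200])

    def test_single_class_rejected(self, simple_doc):
        pairs = [p for p in generate_candidates(simple_doc) if p.label == "positive"]
        with pytest.raises(ClassifierError, match="negative"):
            train_relation_classifier(pairs)


class TestExtractRelations:
    def test_no_attributes_no_relations(self, classifier):
        clf, _ = classifier
        doc = _doc("hemorrhage and exudate", [(Category.LESION, 0, 10), (Category.LESION, 15, 22)])
        assert extract_relations(doc, clf) == []

    def test_untrained_classifier_rejected(self, simple_doc):
        with pytest.raises(ClassifierError):
            extract_relations(simple_doc, RelationClassifier())

    def test_threshold_one_rejects_everything(self, simple_doc, classifier):
        clf, _ = classifier
        strict = RelationClassifier(
            vectorizer=clf.vectorizer, model=clf.model, threshold=1.1
        )
        assert extract_relations(simple_doc, strict) == []

    def test_schema_soundness(self, small_corpus, classifier):
        """Every output relation's type matches its argument categories."""
        clf, _ = classifier
        for doc in small_corpus[:50]:
            for r in extract_relations(doc, clf):
                attr = doc.mention_by_id(r.attribute_id)
                lesion = doc.mention_by_id(r.lesion_id)
                assert lesion.category is Category.LESION
                assert RELATION_FOR_ATTRIBUTE[attr.category] is r.rel_type
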