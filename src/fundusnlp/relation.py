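"""Relation extraction: candidate-pair generation plus binary classification.

Attributes relate to lesions only within one sentence, so candidate
generation enumerates exactly the same-sentence (lesion, attribute)
pairs whose categories admit a relation — a severity never pairs with an
eye part, and mentions in different sentences never pair. Each candidate
is then classified positive/negative; the relation type is not learned
but implied by the attribute's category (the schema admits only one type
per pair).

The reference classifier is a regularized logistic regression over
sparse features concatenating a sentence-level representation (token
bag) with local representations of the two mentions (surfaces,
categories, signed token distance, the tokens between them, and the
number of intervening lesions). Category-conjoined copies of the
positional features let a linear model express per-attribute attachment
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .schema import (
    RELATION_FOR_ATTRIBUTE,
    AnnotatedDocument,
    Category,
    ConceptMention,
    RelationInstance,
    RelationType,
)
from .textproc import Sentence, split_sentences

POSITIVE, NEGATIVE, UNKNOWN = "positive", "negative", "unknown"


class ClassifierError(ValueError):
    pass


@dataclass
class CandidatePair:
    """A same-sentence (lesion, attribute) pair with its schema-implied type."""

    sentence: Sentence
    lesion: ConceptMention
    attribute: ConceptMention
    implied_type: RelationType
    label: str = UNKNOWN
    context_mentions: list[ConceptMention] = field(default_factory=list)


def generate_candidates(
    doc: AnnotatedDocument,
    sentences: list[Sentence] | None = None,
    label_from_gold: bool = True,
) -> list[CandidatePair]:
    """Enumerate schema-legal same-sentence pairs, ordered by offsets.

    With ``label_from_gold`` the doc's relations label each pair positive
    or negative; otherwise labels are ``unknown`` (prediction time).
    """
    if sentences is None:
        sentences = split_sentences(doc.text)
    gold_links = {(r.attribute_id, r.lesion_id) for r in doc.relations}
    pairs: list[CandidatePair] = []
    for sent in sentences:
        in_sent = sorted(
            (m for m in doc.mentions if sent.contains(m.start, m.end)),
            key=lambda m: (m.start, m.end),
        )
        lesions = [m for m in in_sent if m.category is Category.LESION]
        attributes = [m for m in in_sent if m.category is not Category.LESION]
        for lesion in lesions:
            for attr in attributes:
                if label_from_gold:
                    label = POSITIVE if (attr.id, lesion.id) in gold_links else NEGATIVE
                else:
                    label = UNKNOWN
                pairs.append(
                    CandidatePair(
                        sentence=sent,
                        lesion=lesion,
                        attribute=attr,
                        implied_type=RELATION_FOR_ATTRIBUTE[attr.category],
                        label=label,
                        context_mentions=in_sent,
                    )
                )
    return pairs


def _token_span(sent: Sentence, m: ConceptMention) -> tuple[int, int]:
    idx = [i for i, t in enumerate(sent.tokens) if t.start < m.end and m.start < t.end]
    return (idx[0], idx[-1] + 1) if idx else (0, 0)


def featurize(pair: CandidatePair) -> dict[str, float]:
    """Sparse feature dict for one candidate pair; purely deterministic."""
    sent = pair.sentence
    feats: dict[str, float] = {"bias": 1.0}
    for t in sent.tokens:
        feats[f"sent={t.surface.lower()}"] = 1.0
    feats[f"lesion={pair.lesion.surface.lower()}"] = 1.0
    feats[f"attr={pair.attribute.surface.lower()}"] = 1.0
    cat = pair.attribute.category.value
    feats[f"attr_cat={cat}"] = 1.0

    l_first, l_last = _token_span(sent, pair.lesion)
    a_first, a_last = _token_span(sent, pair.attribute)
    if a_first >= l_last:  # attribute after lesion
        dist = a_first - l_last + 1
        lo, hi = l_last, a_first
    else:  # attribute before lesion
        dist = -(l_first - a_last + 1)
        lo, hi = a_last, l_first
    feats["dist"] = float(dist)
    feats[f"dist_sign={'after' if dist > 0 else 'before'}"] = 1.0
    for t in sent.tokens[lo:hi]:
        feats[f"between={t.surface.lower()}"] = 1.0
    between_chars = (pair.lesion.end, pair.attribute.start) if dist > 0 else (
        pair.attribute.end, pair.lesion.start
    )
    n_between = sum(
        1
        for m in pair.context_mentions
        if m.category is Category.LESION
        and m.id not in (pair.lesion.id, pair.attribute.id)
        and m.start >= between_chars[0]
        and m.end <= between_chars[1]
    )
    feats["between_lesions"] = float(n_between)
    # category-conjoined positional features: attachment is per-attribute-type
    feats[f"{cat}|between_lesions={n_between}"] = 1.0
    feats[f"{cat}|dist_sign={'after' if dist > 0 else 'before'}"] = 1.0
    feats[f"{cat}|dist={min(abs(dist), 8)}"] = 1.0
    return feats


@dataclass
class RelationClassifier:
    """Binary positive/negative classifier over featurized candidate pairs."""

    vectorizer: DictVectorizer | None = None
    model: LogisticRegression | None = None
    threshold: float = 0.5
    seed: int = 0

    @property
    def trained(self) -> bool:
        return self.model is not None

    def decide(self, pairs: list[CandidatePair]) -> list[bool]:
        if not self.trained:
            raise ClassifierError("relation classifier has not been trained")
        if not pairs:
            return []
        X = self.vectorizer.transform([featurize(p) for p in pairs])
        proba = self.model.predict_proba(X)[:, list(self.model.classes_).index(POSITIVE)]
        return [bool(p >= self.threshold) for p in proba]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "RelationClassifier":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a {cls.__name__}")
        return model


def train_relation_classifier(
    pairs: list[CandidatePair],
    C: float = 10.0,
    threshold: float = 0.5,
    seed: int = 0,
) -> RelationClassifier:
    """Fit the reference classifier on labeled candidate pairs."""
    labels = [p.label for p in pairs]
    for required in (POSITIVE, NEGATIVE):
        if required not in labels:
            raise ClassifierError(f"training set contains no {required} examples")
    vec = DictVectorizer(sparse=True)
    X = vec.fit_transform([featurize(p) for p in pairs])
    y = np.array(labels)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X, y)
    return RelationClassifier(vectorizer=vec, model=clf, threshold=threshold, seed=seed)


def extract_relations(
    doc: AnnotatedDocument,
    classifier: RelationClassifier,
    sentences: list[Sentence] | None = None,
) -> list[RelationInstance]:
    """Typed relations for every positive-classified candidate pair."""
    pairs = generate_candidates(doc, sentences=sentences, label_from_gold=False)
    decisions = classifier.decide(pairs)
    relations = []
    for pair, keep in zip(pairs, decisions):
        if keep:
            relations.append(
                RelationInstance(
                    id=f"R{len(relations) + 1}",
                    rel_type=pair.implied_type,
                    attribute_id=pair.attribute.id,
                    lesion_id=pair.lesion.id,
                )
            )
    return relations
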