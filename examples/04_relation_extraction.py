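"""Link attributes to lesions with candidate pairs + binary classification.

Candidates are all same-sentence (lesion, attribute) pairs whose
categories admit a relation; a logistic-regression classifier labels
each pair positive or negative, and the relation type follows from the
attribute category (severity-lesion, located, laterality-lesion).
"""

from fundusnlp import (
    SynthConfig,
    extract_relations,
    generate_candidates,
    generate_corpus,
    split_corpus,
    train_relation_classifier,
)

docs = generate_corpus(SynthConfig(n_docs=300, seed=9))
train, test = split_corpus(docs, 0.8, seed=9)

pairs = [p for d in train for p in generate_candidates(d)]
n_pos = sum(1 for p in pairs if p.label == "positive")
print(f"{len(pairs)} candidate pairs from the training half ({n_pos} positive)")

classifier = train_relation_classifier(pairs, seed=9)

doc = next(d for d in test if len(d.relations) >= 2)
print("\n--- document ---")
print(doc.text)
for r in extract_relations(doc, classifier):
    attr = doc.mention_by_id(r.attribute_id)
    lesion = doc.mention_by_id(r.lesion_id)
    print(f"{r.rel_type.value}: {attr.surface!r} -> {lesion.surface!r}")
print("\nEach line links one attribute mention to the lesion it modifies; "
      "pairs in different sentences are never considered.")
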