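"""Compare the gold-concept and end-to-end relation-extraction settings.

The gold setting feeds gold concept spans to the relation classifier,
isolating relation quality; the end-to-end setting runs the tagger
first, so concept errors propagate into relation scores. Strict and
lenient scores are identical in the gold setting by construction.
"""

from fundusnlp import (
    SynthConfig,
    default_lexicon,
    evaluate_relations,
    generate_candidates,
    generate_corpus,
    split_corpus,
    train_relation_classifier,
    train_tagger,
)
from fundusnlp.pipeline import run_e2e, run_gold_setting

docs = generate_corpus(SynthConfig(n_docs=300, seed=2))
train, test = split_corpus(docs, 0.8, seed=2)

tagger = train_tagger(train, seed=2, log_train_f1=False)
classifier = train_relation_classifier(
    [p for d in train for p in generate_candidates(d)], seed=2
)

gold_preds = run_gold_setting(test, classifier)
gold = evaluate_relations(gold_preds, test, setting="gold")

raw = [d.copy_without_annotations() for d in test]
e2e_preds, _ = run_e2e(raw, tagger, classifier, default_lexicon())
e2e = evaluate_relations(e2e_preds, test, setting="e2e")

print(f"gold-concept setting:  strict F1 {gold.micro.strict.f1:.4f}  "
      f"lenient F1 {gold.micro.lenient.f1:.4f}")
print(f"end-to-end setting:    strict F1 {e2e.micro.strict.f1:.4f}  "
      f"lenient F1 {e2e.micro.lenient.f1:.4f}")
print("\nThe end-to-end score can only fall below the gold setting, since "
      "it additionally depends on predicted concept spans.")
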