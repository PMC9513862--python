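"""Generate a small synthetic fundus-report corpus and inspect one document.

The generator emulates the structure of clinical fundus-image reports:
lesion mentions with optional severity / eye-part / laterality attributes,
same-sentence relations, negation cues, and unannotated filler sentences.
"""

from fundusnlp import SynthConfig, generate_corpus, write_ann

docs = generate_corpus(SynthConfig(n_docs=10, seed=7))
doc = docs[0]

print("--- report text ---")
print(doc.text)
print("--- brat standoff annotations ---")
print(write_ann(doc))
n_mentions = sum(len(d.mentions) for d in docs)
n_relations = sum(len(d.relations) for d in docs)
n_negated = sum(1 for d in docs for m in d.mentions if m.negated)
print(f"{len(docs)} documents, {n_mentions} concept mentions, "
      f"{n_relations} relations, {n_negated} negated lesions")
print("Each T line is a typed span, each R line links an attribute to a "
      "lesion, each A line marks a negated lesion.")
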