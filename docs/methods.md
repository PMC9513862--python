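# Methods

## Problem and schema

Fundus image reports describe retinal findings in short, fragmentary
clinical prose. The extraction target is a typed graph per report: concept
mentions in four categories — `lesion` (hemorrhage, exudate, ...),
`eye_part` (macula, optic disc, ...), `laterality` (right/left/both eye,
OD/OS/OU), `severity` (mild/moderate/severe) — plus a boolean negation flag
on lesions, and three relation types each linking one attribute category to
a lesion (`located` for eye parts, `laterality-lesion`, `severity-lesion`).
Because the relation type is a function of the attribute category, relation
extraction is a binary decision per candidate pair, not a multi-class
problem.

Offsets are 0-based, end-exclusive, in Unicode code points, everywhere —
the brat standoff convention. On read, label spellings are matched
case-insensitively, either argument order is accepted when the categories
disambiguate it, and discontinuous spans are collapsed to their envelope
with a warning (the schema gives no use for them); on write, canonical
spellings and attribute-first argument order are produced. Parsing never
silently drops an annotation line: each `T`/`R`/`A` line is consumed or
raises a structured error naming the line.

## Text processing

The sentence splitter is rule-based: terminal punctuation (`.!?`) followed
by whitespace ends a sentence, and a hard newline always ends one, because
report fields frequently lack terminal punctuation. Any splitter meeting
the same postconditions (ordered, non-overlapping, covering all
non-whitespace text) would be conformant; this one is deterministic and
dependency-free. Tokens are maximal word-character runs or single
punctuation marks, and tokenization is offset-faithful by construction
(`text[t.start:t.end] == t.surface`).

Spans are encoded as BIO (not BIOES); an illegal `I-X` opening is repaired
by promotion to `B-X`, which is lossless for this schema. A mention
boundary that falls inside a token is snapped **outward** to the smallest
covering token span, with a warning — outward snapping favors lenient-match
recall and never truncates a mention.

## Concept tagger

The reference tagger is an averaged structured perceptron — a linear-chain
conditional sequence labeler trained by Viterbi-based mistake-driven
updates, with per-epoch weight averaging. Features per token: lowercased
surface, 3- and 4-character suffixes, word shape, the lowercased tokens at
offsets ±1 and ±2, and membership in per-category lexicons harvested from
the training gold only. Transition weights are learned; decoding masks
illegal transitions (`I-X` after anything other than `B-X`/`I-X`) at −10⁹
and breaks exact ties by label-inventory order, so prediction is a pure
function of the trained state. Defaults: 8 epochs (training stops early
when an epoch makes no mistakes), seed-controlled shuffling. Hyperparameters
are an independent choice documented here; nothing in the schema pins them.

Contextual-encoder taggers (BERT-family) are supported as a design point
through the `SequenceTagger` protocol — anything with
`predict_labels(sentence)` can drive `predict_mentions` and the e2e
pipeline — but the shipped implementation is the perceptron: it is
deterministic, CPU-only, and sufficient for the synthetic benchmark.

## Negation

Detection follows the classic NegEx scheme: a lesion is negated when a
pre-negation trigger ends within `window` tokens before it (or a
post-negation trigger begins within `window` tokens after it) and no
termination or pseudo-negation trigger intervenes. The default window is 5
tokens, the classic choice; it is configurable. Multi-word triggers are
matched greedily, longest first, case-insensitively. The shipped default
lexicon is deliberately compact and auditable (pre: *no, denies, without,
no evidence of, negative for*; post: *ruled out*; pseudo: *no increase, no
change*; termination: *but, however, except*); a fuller lexicon can be
loaded from a `phrase<TAB>role` file. Negation applies to lesion mentions
only.

Customization mines pre-negation candidates — unigrams and bigrams within
the window before gold-negated lesions — and admits a candidate iff it
precedes at least two gold-negated mentions and adding it does not decrease
training-set accuracy, processing candidates in frequency-then-lexicographic
order. The admission rule makes improvement monotone by construction and the
procedure deterministic. It is fully automatic; a deployment could add a
human curation pass over the admitted phrases, which this package does not
model. The rule admits harmless fragments of longer cues (e.g. *of*,
*evidence of*) along with the true cues; they never reduce accuracy on the
corpus they were mined from, but a curator would likely strip them.

## Relation classification

Candidate generation is exactly the same-sentence, schema-legal cross
product: every (lesion, attribute) pair within one sentence, and nothing
else. Gold relations that cross sentence boundaries — possible in real
data, impossible in the synthetic corpus — are therefore unreachable and
count as recall misses, which matches how same-sentence heuristics behave
on real reports. All non-gold same-sentence legal pairs serve as negative
examples; no subsampling.

The reference classifier is L2-regularized logistic regression (C=10,
threshold 0.5, both configurable) over sparse features concatenating a
sentence-level representation with two concept-level ones: the sentence
token bag, both mention surfaces and the attribute category, signed token
distance between the mentions, the tokens between them, and the number of
intervening lesion mentions — plus attribute-category-conjoined copies of
the positional features, so a linear model can express that severity
attaches backward-adjacent while laterality attaches to the nearest
preceding lesion.

## Evaluation protocol

Strict matching requires identical (start, end) and category; lenient
requires ≥ 1 shared character (the common clinical-NLP convention;
configurable) and the same category. Matching is one-to-one, greedy in
gold offset order with an earliest-offset tie-break among candidate
predictions; tests cross-check it against an exhaustive maximum-assignment
oracle. A predicted relation is correct iff its type matches and **both**
arguments match gold arguments under the active mode (both-lenient in
lenient mode — mixed strict/lenient matching is not used). Micro averages
pool tp/n_pred/n_gold before computing P/R/F1; per-category rows and the
pooled row are both reported, and the report object enforces that micro
counts equal category sums and that lenient tp ≥ strict tp row by row. In
the gold-concept setting strict ≡ lenient is enforced as an invariant.
When a denominator is zero the metric is reported as 0.0 and the row
carries a zero-support flag. Cohen's kappa for token-level agreement is
computed over the 9-label BIO alphabet (via scikit-learn, with an explicit
guard returning 1.0 on exact agreement, where chance agreement can
degenerate).

## Synthetic corpus

The generator emits template-grammar sentences,

    [<cue> ][<severity> ]<lesion>[ and <lesion>][ in the <eye part>][ of the <laterality>].

mixed with unannotated distractor sentences, from a single seeded PRNG
stream per corpus. Attributes attach to the *nearest* lesion: severity to
the lesion it directly precedes, eye part and laterality to the closest
preceding lesion — a deterministic rule a classifier can recover, with the
two-lesion conjunction frames supplying genuine negative candidate pairs.
Negated frames are single-lesion so the gold flag is exactly "a cue opens
the sentence" and stays consistent with a 5-token detection window. Two of
the generator's cue phrases (*free of*, *absence of*) are deliberately
absent from the default detection lexicon so that trigger mining has
something real to discover.

Defaults emulate the distributional shape of an annotated corpus of 536
reports from a retinopathy clinic: 536 documents, 3–8 sentences each,
negation rate 0.24 of lesion mentions, per-lesion attribute rates 0.54
(laterality), 0.25 (severity), 0.02 (eye part), distractor and two-lesion
rates 0.25 each. The benchmark used by tests and `scripts/acceptance.py`
scales this to 1000 documents with an exact `round(n·0.8)` document-level
8:2 split (the reference corpus's own 391/145 split is close to but not
exactly 8:2; exact rounding is used deliberately).

What the generator does **not** emulate: report headers and institutional
boilerplate, misspellings, abbreviations beyond OD/OS/OU, cross-sentence
relations, overlapping or discontinuous mentions, hedged/uncertain
findings, and lexical variety beyond the configured vocabularies. Passing
scores on this corpus therefore demonstrate that the pipeline's machinery —
encoding, decoding, pairing, scoring — is correct and self-consistent, not
that the reference models reach any particular accuracy on real clinical
text; on real reports the tagger and classifier would need richer features
or a contextual encoder, and scores in the high-0.8s/low-0.9s rather than
saturation are the realistic regime.

## Numerical and degenerate-input conventions

F1 is defined as 0 when P = R = 0. Empty text yields empty sentence lists,
empty documents pass through the pipeline untouched, and an e2e stage
failure aborts only that document (emitted unannotated) while the run
summary records the per-document status. Training refuses an empty corpus,
a corpus with zero mentions, and a single-class relation training set, each
with a diagnostic naming the problem. Corpus-level scoring requires the
predicted and gold corpora to be aligned by document id and raises
otherwise.

## Known limitations

- The same-sentence heuristic bounds relation recall on corpora with
  cross-sentence relations.
- Trigger mining optimizes training accuracy only; it cannot reject a cue
  that helps on the training corpus but harms elsewhere.
- The greedy one-to-one matcher can in principle differ from the maximum
  assignment on pathologically overlapping prediction sets; the exhaustive
  oracle in the test suite bounds this on realistic fixtures.
- Uncertainty, hypothetical and family-history contexts (ConText-style
  extensions) are out of scope, as are brat event/normalization/note line
  types.
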