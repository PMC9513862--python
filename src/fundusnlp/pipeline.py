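"""The two experimental settings, assembled end to end.

* gold-concept setting: gold mentions are passed through untouched and
  only the relation classifier runs — isolating relation-classification
  quality from tagging errors.
* end-to-end (e2e) setting: the tagger predicts mentions, negation runs
  over the predicted lesions, and the relation classifier runs over
  predicted mentions — compounding tagging errors into relation scores.

Negation runs in the e2e path only; the gold setting evaluates relation
classification in isolation and negation is scored separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .negation import DEFAULT_WINDOW, TriggerLexicon, apply_negation
from .ner import SequenceTagger, predict_mentions
from .relation import RelationClassifier, extract_relations
from .schema import AnnotatedDocument
from .textproc import split_sentences

logger = logging.getLogger(__name__)


@dataclass
class RunSummary:
    """Per-document status of a pipeline run."""

    status: dict[str, str] = field(default_factory=dict)  # doc_id -> "ok" | error text

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.status.values() if s != "ok")


def run_gold_setting(
    gold_docs: list[AnnotatedDocument], classifier: RelationClassifier
) -> list[AnnotatedDocument]:
    """Re-predict relations over gold mentions; mentions pass through unchanged."""
    out = []
    for doc in gold_docs:
        sentences = split_sentences(doc.text)
        pred = AnnotatedDocument(
            doc_id=doc.doc_id,
            text=doc.text,
            mentions=list(doc.mentions),
            relations=extract_relations(doc, classifier, sentences=sentences),
        )
        pred.validate()
        out.append(pred)
    return out


def run_e2e(
    raw_docs: list[AnnotatedDocument],
    tagger: SequenceTagger,
    classifier: RelationClassifier,
    lexicon: TriggerLexicon,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[AnnotatedDocument], RunSummary]:
    """Tag, negate, and relate raw text; a failing document is emitted empty."""
    out = []
    summary = RunSummary()
    for doc in raw_docs:
        pred = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
        try:
            sentences = split_sentences(doc.text)
            pred.mentions = predict_mentions(tagger, doc.text)
            apply_negation(pred, lexicon, window=window, sentences=sentences)
            pred.relations = extract_relations(pred, classifier, sentences=sentences)
            pred.validate()
            summary.status[doc.doc_id] = "ok"
        except Exception as exc:  # abort this document, keep the run going
            logger.error("document %s failed: %s", doc.doc_id, exc)
            pred = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
            summary.status[doc.doc_id] = f"error: {exc}"
        out.append(pred)
    return out, summary
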