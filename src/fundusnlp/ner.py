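"""Concept extraction: a linear-chain sequence labeler over BIO tokens.

The reference tagger is an averaged structured perceptron with Viterbi
decoding — a linear-chain conditional model with hand-crafted features
(lowercased token, suffixes, word shape, a +/-2 token context window,
and membership in per-category lexicons harvested from the training
gold). It is deterministic given a seed, trains in seconds on one CPU,
and needs no pretrained weights. Contextual-encoder taggers (BERT-style)
can be plugged in through the same :class:`SequenceTagger` protocol.

Decoding forbids illegal transitions (an I-X may only follow B-X or
I-X); ties are broken by label-inventory order.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import joblib
import numpy as np

from .schema import AnnotatedDocument, Category, ConceptMention
from .textproc import (
    BIO_LABELS,
    Sentence,
    Token,
    bio_to_spans,
    spans_to_bio,
    split_sentences,
)

logger = logging.getLogger(__name__)

_NEG_INF = -1e9


class TrainingError(ValueError):
    pass


@runtime_checkable
class SequenceTagger(Protocol):
    """Contract for pluggable taggers (reference or contextual-encoder)."""

    def predict_labels(self, sentence: Sentence) -> list[str]: ...


def _shape(w: str) -> str:
    out = []
    for ch in w:
        s = "X" if ch.isupper() else "x" if ch.islower() else "d" if ch.isdigit() else ch
        if not out or out[-1] != s:
            out.append(s)
    return "".join(out)


def token_features(tokens: list[Token], i: int, lexicons: dict[str, frozenset[str]]) -> list[str]:
    w = tokens[i].surface
    lw = w.lower()
    feats = [
        "bias",
        f"w={lw}",
        f"suf3={lw[-3:]}",
        f"suf4={lw[-4:]}",
        f"shape={_shape(w)}",
    ]
    for off in (-2, -1, 1, 2):
        j = i + off
        ctx = tokens[j].surface.lower() if 0 <= j < len(tokens) else ("<s>" if j < 0 else "</s>")
        feats.append(f"w[{off}]={ctx}")
    for cat, vocab in lexicons.items():
        if lw in vocab:
            feats.append(f"lex={cat}")
    return feats


def _legal_transitions(labels: tuple[str, ...]) -> np.ndarray:
    """mask[i, j] — may label j follow label i? I-X only after B-X / I-X."""
    n = len(labels)
    mask = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if b.startswith("I-"):
                mask[i, j] = a.endswith(b[2:]) and a != "O"
            else:
                mask[i, j] = True
    return mask


@dataclass
class PerceptronTagger:
    """Averaged structured perceptron; state is plain numpy arrays."""

    labels: tuple[str, ...] = BIO_LABELS
    feat_index: dict[str, int] = field(default_factory=dict)
    emission: np.ndarray | None = None  # (n_features, n_labels)
    transition: np.ndarray | None = None  # (n_labels, n_labels)
    start: np.ndarray | None = None  # (n_labels,)
    lexicons: dict[str, frozenset[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def trained(self) -> bool:
        return self.emission is not None

    def _feature_ids(self, tokens: list[Token], grow: bool = False) -> list[list[int]]:
        rows = []
        for i in range(len(tokens)):
            ids = []
            for f in token_features(tokens, i, self.lexicons):
                idx = self.feat_index.get(f)
                if idx is None and grow:
                    idx = self.feat_index[f] = len(self.feat_index)
                if idx is not None:
                    ids.append(idx)
            rows.append(ids)
        return rows

    def _viterbi(self, fid_rows: list[list[int]], W: np.ndarray, T: np.ndarray, S: np.ndarray) -> list[int]:
        n, L = len(fid_rows), len(self.labels)
        if n == 0:
            return []
        emit = np.stack([W[ids].sum(axis=0) if ids else np.zeros(L) for ids in fid_rows])
        trans = np.where(self._mask, T, _NEG_INF)
        illegal_start = np.array([lab.startswith("I-") for lab in self.labels])
        score = emit[0] + S + np.where(illegal_start, _NEG_INF, 0.0)
        back = np.zeros((n, L), dtype=np.int64)
        for t in range(1, n):
            cand = score[:, None] + trans  # (from, to)
            back[t] = cand.argmax(axis=0)
            score = cand.max(axis=0) + emit[t]
        path = [int(score.argmax())]
        for t in range(n - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        return path[::-1]

    def predict_labels(self, sentence: Sentence) -> list[str]:
        if not self.trained:
            raise TrainingError("tagger has not been trained")
        fid_rows = self._feature_ids(sentence.tokens)
        path = self._viterbi(fid_rows, self.emission, self.transition, self.start)
        return [self.labels[i] for i in path]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "PerceptronTagger":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a {cls.__name__}")
        return model

    # populated during training
    _mask: np.ndarray | None = None


def _harvest_lexicons(train_docs: list[AnnotatedDocument]) -> dict[str, frozenset[str]]:
    """Per-category sets of mention tokens, from training gold only."""
    buckets: dict[str, set[str]] = {c.value: set() for c in Category}
    for doc in train_docs:
        for m in doc.mentions:
            buckets[m.category.value].update(w.lower() for w in m.surface.split())
    return {c: frozenset(v) for c, v in buckets.items() if v}


def train_tagger(
    train_docs: list[AnnotatedDocument],
    epochs: int = 8,
    seed: int = 0,
    log_train_f1: bool = True,
) -> PerceptronTagger:
    """Train the reference tagger on gold-annotated documents."""
    if not train_docs:
        raise TrainingError("training corpus is empty")
    if not any(d.mentions for d in train_docs):
        raise TrainingError(
            "training corpus contains no concept mentions (all tokens would be labeled O)"
        )
    model = PerceptronTagger(lexicons=_harvest_lexicons(train_docs))
    model._mask = _legal_transitions(model.labels)
    label_idx = {lab: i for i, lab in enumerate(model.labels)}

    examples: list[tuple[list[list[int]], list[int]]] = []
    for doc in train_docs:
        sentences = split_sentences(doc.text)
        for sent in sentences:
            in_sent = [m for m in doc.mentions if sent.contains(m.start, m.end)]
            gold = spans_to_bio(sent.tokens, in_sent)
            fid_rows = model._feature_ids(sent.tokens, grow=True)
            examples.append((fid_rows, [label_idx[g] for g in gold]))

    F, L = len(model.feat_index), len(model.labels)
    W = np.zeros((F, L))
    T = np.zeros((L, L))
    S = np.zeros(L)
    W_acc, T_acc, S_acc = np.zeros_like(W), np.zeros_like(T), np.zeros_like(S)
    rng = random.Random(seed)
    order = list(range(len(examples)))
    for _epoch in range(epochs):
        rng.shuffle(order)
        mistakes = 0
        for k in order:
            fid_rows, gold = examples[k]
            pred = model._viterbi(fid_rows, W, T, S)
            if pred == gold:
                continue
            mistakes += 1
            for t, ids in enumerate(fid_rows):
                if pred[t] != gold[t]:
                    W[ids, gold[t]] += 1.0
                    W[ids, pred[t]] -= 1.0
            if gold and pred:
                S[gold[0]] += 1.0
                S[pred[0]] -= 1.0
            for t in range(1, len(gold)):
                T[gold[t - 1], gold[t]] += 1.0
                T[pred[t - 1], pred[t]] -= 1.0
        W_acc += W
        T_acc += T
        S_acc += S
        logger.info("epoch %d: %d/%d sentences updated", _epoch + 1, mistakes, len(examples))
        if mistakes == 0:
            # converged; remaining epochs would accumulate identical weights
            remaining = epochs - _epoch - 1
            W_acc += remaining * W
            T_acc += remaining * T
            S_acc += remaining * S
            break
    model.emission = W_acc / epochs
    model.transition = T_acc / epochs
    model.start = S_acc / epochs
    model.meta = {"epochs": epochs, "seed": seed, "n_features": F}
    if log_train_f1:
        from .evaluation import evaluate_concepts

        preds = [
            AnnotatedDocument(d.doc_id, d.text, predict_mentions(model, d.text))
            for d in train_docs
        ]
        report = evaluate_concepts(preds, train_docs)
        model.meta["train_lenient_f1"] = report.micro.lenient.f1
        logger.info("training-set lenient F1: %.4f", report.micro.lenient.f1)
    return model


def predict_mentions(model: SequenceTagger, doc_text: str) -> list[ConceptMention]:
    """Tag a raw document; mentions are decoded sentence by sentence.

    Output mentions never overlap, carry valid offsets, and are re-numbered
    T1.. in offset order.
    """
    mentions: list[ConceptMention] = []
    for sent in split_sentences(doc_text):
        labels = model.predict_labels(sent)
        mentions.extend(bio_to_spans(sent.tokens, labels, text=doc_text))
    mentions.sort(key=lambda m: (m.start, m.end))
    for k, m in enumerate(mentions, start=1):
        m.id = f"T{k}"
    return mentions
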