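"""NegEx-style negation detection and corpus-driven trigger mining.

A lesion mention is negated when a pre-negation trigger phrase occurs
within a fixed token window before it (or a post-negation trigger within
the window after it), with no termination trigger ("but", "however", ...)
and no pseudo-negation trigger between the trigger and the mention.
Matching is case-insensitive on token sequences; multi-word triggers are
matched greedily, longest first.

Rule lexicons ported across institutions lose coverage, so the lexicon
can be extended from a training corpus: candidate unigrams/bigrams that
precede gold-negated lesions are admitted as pre-negation triggers when
they recur and do not hurt training-set accuracy.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .schema import AnnotatedDocument, Category, ConceptMention
from .textproc import Sentence, sentence_of, split_sentences, tokenize

logger = logging.getLogger(__name__)

ROLES = ("pre_negation", "post_negation", "pseudo_negation", "termination")

DEFAULT_WINDOW = 5


class LexiconError(ValueError):
    pass


def _normalize(phrase: str) -> str:
    return " ".join(phrase.lower().split())


@dataclass
class TriggerLexicon:
    """Phrases with roles; each phrase holds exactly one role."""

    entries: dict[str, str] = field(default_factory=dict)  # phrase -> role

    def _token_index(self) -> dict[str, list[tuple[tuple[str, ...], str]]]:
        """First-token index of tokenized phrases, longest first; cached."""
        cached = self.__dict__.get("_index_cache")
        if cached is not None and cached[0] == len(self.entries):
            return cached[1]
        index: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for phrase, role in self.entries.items():
            ptoks = tuple(t.surface.lower() for t in tokenize(phrase))
            if ptoks:
                index.setdefault(ptoks[0], []).append((ptoks, role))
        for lst in index.values():
            lst.sort(key=lambda pr: -len(pr[0]))
        self.__dict__["_index_cache"] = (len(self.entries), index)
        return index

    def add(self, phrase: str, role: str) -> None:
        phrase = _normalize(phrase)
        if role not in ROLES:
            raise LexiconError(f"unknown trigger role {role!r}")
        if not phrase:
            raise LexiconError("empty trigger phrase")
        if self.entries.get(phrase, role) != role:
            raise LexiconError(
                f"phrase {phrase!r} already has role {self.entries[phrase]!r}, cannot add as {role!r}"
            )
        self.entries[phrase] = role

    def __contains__(self, phrase: str) -> bool:
        return _normalize(phrase) in self.entries

    def copy(self) -> "TriggerLexicon":
        return TriggerLexicon(entries=dict(self.entries))

    def phrases_by_role(self, role: str) -> list[str]:
        return sorted(p for p, r in self.entries.items() if r == role)

    def save(self, path: str | Path) -> None:
        lines = [f"{p}\t{r}" for p, r in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TriggerLexicon":
        lex = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            try:
                phrase, role = line.split("\t")
            except ValueError as exc:
                raise LexiconError(f"malformed lexicon line: {line!r}") from exc
            lex.add(phrase, role)
        return lex


def default_lexicon() -> TriggerLexicon:
    """Compact built-in lexicon of common clinical negation triggers."""
    lex = TriggerLexicon()
    for p in ("no", "denies", "without", "no evidence of", "negative for"):
        lex.add(p, "pre_negation")
    for p in ("ruled out",):
        lex.add(p, "post_negation")
    for p in ("no increase", "no change"):
        lex.add(p, "pseudo_negation")
    for p in ("but", "however", "except"):
        lex.add(p, "termination")
    return lex


def _match_triggers(tokens: list[str], lexicon: TriggerLexicon) -> list[tuple[int, int, str]]:
    """Greedy longest-first, left-to-right trigger matches as (start, end, role)."""
    index = lexicon._token_index()
    matches: list[tuple[int, int, str]] = []
    lowered = [t.lower() for t in tokens]
    i = 0
    while i < len(lowered):
        hit = None
        for ptoks, role in index.get(lowered[i], ()):  # longest first
            if tuple(lowered[i : i + len(ptoks)]) == ptoks:
                hit = (len(ptoks), role)
                break
        if hit:
            matches.append((i, i + hit[0], hit[1]))
            i += hit[0]
        else:
            i += 1
    return matches


def detect_negation(
    sentence: Sentence,
    mention: ConceptMention,
    lexicon: TriggerLexicon,
    window: int = DEFAULT_WINDOW,
) -> bool:
    """Is a lesion mention inside this sentence negated?"""
    if not sentence.contains(mention.start, mention.end):
        raise ValueError(
            f"mention ({mention.start}, {mention.end}) lies outside sentence "
            f"({sentence.start}, {sentence.end})"
        )
    tok_idx = [
        i for i, t in enumerate(sentence.tokens) if t.start < mention.end and mention.start < t.end
    ]
    if not tok_idx:
        return False
    m_first, m_last = tok_idx[0], tok_idx[-1]
    surfaces = [t.surface for t in sentence.tokens]
    matches = _match_triggers(surfaces, lexicon)

    def blocked(lo: int, hi: int) -> bool:
        return any(
            lo <= s < hi and role in ("termination", "pseudo_negation")
            for s, _e, role in matches
        )

    for s, e, role in matches:
        if role == "pre_negation" and e <= m_first and m_first - e <= window:
            if not blocked(e, m_first):
                return True
        if role == "post_negation" and s > m_last and s - m_last - 1 <= window:
            if not blocked(m_last + 1, s):
                return True
    return False


def apply_negation(
    doc: AnnotatedDocument,
    lexicon: TriggerLexicon,
    window: int = DEFAULT_WINDOW,
    sentences: list[Sentence] | None = None,
) -> None:
    """Set ``negated`` in place on every lesion mention of the document."""
    if sentences is None:
        sentences = split_sentences(doc.text)
    for m in doc.mentions:
        if m.category is not Category.LESION:
            continue
        sent = sentence_of(sentences, m)
        m.negated = detect_negation(sent, m, lexicon, window) if sent else False


def negation_accuracy(
    pred_docs: list[AnnotatedDocument], gold_docs: list[AnnotatedDocument]
) -> float:
    """Fraction of gold lesion mentions whose predicted negation flag is correct.

    A gold lesion with no exact-span predicted counterpart counts as
    predicted non-negated.
    """
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(pred_by_id) != {d.doc_id for d in gold_docs}:
        raise ValueError("pred and gold corpora are not aligned by doc_id")
    correct = total = 0
    for gold in gold_docs:
        pred = pred_by_id[gold.doc_id]
        flags = {
            (m.start, m.end): m.negated
            for m in pred.mentions
            if m.category is Category.LESION
        }
        for g in gold.mentions:
            if g.category is not Category.LESION:
                continue
            total += 1
            if flags.get((g.start, g.end), False) == g.negated:
                correct += 1
    return correct / total if total else 1.0


def _evaluate_lexicon(
    docs: list[AnnotatedDocument],
    sentence_cache: dict[str, list[Sentence]],
    lexicon: TriggerLexicon,
    window: int,
) -> float:
    correct = total = 0
    for doc in docs:
        sentences = sentence_cache[doc.doc_id]
        for m in doc.mentions:
            if m.category is not Category.LESION:
                continue
            total += 1
            sent = sentence_of(sentences, m)
            pred = detect_negation(sent, m, lexicon, window) if sent else False
            if pred == m.negated:
                correct += 1
    return correct / total if total else 1.0


def mine_triggers(
    train_docs: list[AnnotatedDocument],
    base: TriggerLexicon,
    window: int = DEFAULT_WINDOW,
) -> TriggerLexicon:
    """Extend ``base`` with pre-negation triggers mined from gold flags.

    Candidates are unigrams/bigrams occurring within ``window`` tokens
    before gold-negated lesion mentions. A candidate is admitted iff it
    precedes at least 2 gold-negated mentions and adding it does not
    decrease training-set negation accuracy. Candidates are processed in
    frequency-then-lexicographic order, so mining is deterministic.
    """
    sentence_cache = {d.doc_id: split_sentences(d.text) for d in train_docs}
    counts: Counter[str] = Counter()
    for doc in train_docs:
        for m in doc.mentions:
            if m.category is not Category.LESION or not m.negated:
                continue
            sent = sentence_of(sentence_cache[doc.doc_id], m)
            if sent is None:
                continue
            tok_idx = [
                i for i, t in enumerate(sent.tokens) if t.start < m.end and m.start < t.end
            ]
            if not tok_idx:
                continue
            first = tok_idx[0]
            lo = max(0, first - window)
            before = [t.surface.lower() for t in sent.tokens[lo:first]]
            seen = set()
            for i in range(len(before)):
                seen.add(before[i])
                if i + 1 < len(before):
                    seen.add(f"{before[i]} {before[i + 1]}")
            counts.update(seen)  # one count per preceded negated mention
    if not counts:
        logger.warning("no gold-negated lesions in training corpus; returning base lexicon")
        return base.copy()

    mined = base.copy()
    accuracy = _evaluate_lexicon(train_docs, sentence_cache, mined, window)
    for phrase, freq in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if freq < 2 or phrase in mined:
            continue
        trial = mined.copy()
        trial.add(phrase, "pre_negation")
        trial_acc = _evaluate_lexicon(train_docs, sentence_cache, trial, window)
        if trial_acc >= accuracy:
            mined, accuracy = trial, trial_acc
            logger.info("admitted trigger %r (freq %d, accuracy %.4f)", phrase, freq, accuracy)
    return mined
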