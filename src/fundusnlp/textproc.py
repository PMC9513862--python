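"""Sentence segmentation, offset-faithful tokenization, and BIO coding.

Clinical reports are fragmentary: lines frequently lack terminal
punctuation, so a hard newline is always a sentence boundary in addition
to terminal punctuation (``.``, ``!``, ``?``) followed by whitespace.
Tokens are maximal runs of word characters or single punctuation marks;
``doc_text[t.start:t.end] == t.surface`` holds for every token.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .schema import Category, ConceptMention

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_SENT_BREAK_RE = re.compile(r"[.!?]+(?=\s|$)")

#: Fixed BIO label inventory; order matters (decoding tie-break).
BIO_LABELS = (
    "O",
    "B-Lesion", "I-Lesion",
    "B-Eye_part", "I-Eye_part",
    "B-Laterality", "I-Laterality",
    "B-Severity", "I-Severity",
)

_BIO_SUFFIX = {
    Category.LESION: "Lesion",
    Category.EYE_PART: "Eye_part",
    Category.LATERALITY: "Laterality",
    Category.SEVERITY: "Severity",
}
_SUFFIX_TO_CATEGORY = {v: k for k, v in _BIO_SUFFIX.items()}


class BioError(ValueError):
    pass


@dataclass
class Token:
    surface: str
    start: int
    end: int


@dataclass
class Sentence:
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


def tokenize(sentence_text: str, offset: int = 0) -> list[Token]:
    """Split text into word/punctuation tokens with document-absolute offsets."""
    return [
        Token(m.group(), offset + m.start(), offset + m.end())
        for m in _TOKEN_RE.finditer(sentence_text)
    ]


def split_sentences(text: str) -> list[Sentence]:
    """Segment a report into tokenized sentences.

    Boundaries: terminal punctuation followed by whitespace, and every
    newline. Sentences are trimmed of surrounding whitespace, so they are
    non-overlapping, ordered, and jointly cover all non-whitespace text.
    """
    sentences: list[Sentence] = []
    line_start = 0
    for line in text.split("\n"):
        seg_start = 0
        for m in _SENT_BREAK_RE.finditer(line):
            _append_sentence(sentences, line, seg_start, m.end(), line_start)
            seg_start = m.end()
        _append_sentence(sentences, line, seg_start, len(line), line_start)
        line_start += len(line) + 1
    return sentences


def _append_sentence(out: list[Sentence], line: str, seg_start: int, seg_end: int, line_offset: int) -> None:
    segment = line[seg_start:seg_end]
    stripped = segment.strip()
    if not stripped:
        return
    lead = len(segment) - len(segment.lstrip())
    start = line_offset + seg_start + lead
    end = start + len(stripped)
    out.append(Sentence(start=start, end=end, tokens=tokenize(stripped, offset=start)))


def spans_to_bio(tokens: list[Token], mentions: list[ConceptMention]) -> list[str]:
    """Encode mention spans as BIO labels aligned 1:1 with ``tokens``.

    A mention boundary that falls inside a token is snapped outward to the
    smallest covering token span (with a warning). Two mentions claiming
    the same token raise :class:`BioError` naming both.
    """
    labels = ["O"] * len(tokens)
    owner: list[ConceptMention | None] = [None] * len(tokens)
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        idx = [i for i, t in enumerate(tokens) if t.start < m.end and m.start < t.end]
        if not idx:
            logger.warning("mention %s (%d, %d) covers no token; skipped", m.id, m.start, m.end)
            continue
        first, last = idx[0], idx[-1]
        if tokens[first].start != m.start or tokens[last].end != m.end:
            logger.warning(
                "mention %s (%d, %d) snapped outward to token span (%d, %d)",
                m.id, m.start, m.end, tokens[first].start, tokens[last].end,
            )
        for i in range(first, last + 1):
            if owner[i] is not None:
                raise BioError(
                    f"mentions {owner[i].id} and {m.id} both claim token "
                    f"{tokens[i].surface!r} at ({tokens[i].start}, {tokens[i].end})"
                )
            owner[i] = m
        suffix = _BIO_SUFFIX[m.category]
        labels[first] = f"B-{suffix}"
        for i in range(first + 1, last + 1):
            labels[i] = f"I-{suffix}"
    return labels


def repair_bio(labels: list[str]) -> list[str]:
    """Promote illegal I-X openings (after O, start, or a different type) to B-X."""
    repaired = list(labels)
    prev = "O"
    for i, lab in enumerate(repaired):
        if lab.startswith("I-"):
            suffix = lab[2:]
            if prev == "O" or prev[2:] != suffix:
                repaired[i] = f"B-{suffix}"
        prev = repaired[i]
    return repaired


def bio_to_spans(
    tokens: list[Token],
    labels: list[str],
    text: str | None = None,
    id_prefix: str = "T",
    id_start: int = 1,
) -> list[ConceptMention]:
    """Decode BIO labels into concept mentions.

    Maximal ``B-X (I-X)*`` runs become mentions spanning from the first
    token's start to the last token's end. Illegal I-openings are repaired
    to B first. ``text`` supplies exact surfaces; without it, token
    surfaces are joined with single spaces.
    """
    if len(labels) != len(tokens):
        raise BioError(f"{len(labels)} labels for {len(tokens)} tokens")
    labels = repair_bio(labels)
    mentions: list[ConceptMention] = []
    i = 0
    k = id_start
    while i < len(labels):
        lab = labels[i]
        if lab.startswith("B-"):
            suffix = lab[2:]
            j = i + 1
            while j < len(labels) and labels[j] == f"I-{suffix}":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            surface = text[start:end] if text is not None else " ".join(
                t.surface for t in tokens[i:j]
            )
            mentions.append(
                ConceptMention(
                    id=f"{id_prefix}{k}",
                    category=_SUFFIX_TO_CATEGORY[suffix],
                    start=start,
                    end=end,
                    surface=surface,
                )
            )
            k += 1
            i = j
        else:
            i += 1
    return mentions


def sentence_of(sentences: list[Sentence], mention: ConceptMention) -> Sentence | None:
    """The sentence containing the mention span, or None."""
    for s in sentences:
        if s.contains(mention.start, mention.end):
            return s
    return None
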