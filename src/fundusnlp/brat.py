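"""Reading and writing brat standoff annotation (.txt/.ann pairs).

Supported line types:

* ``T<k>\\t<Label> <start> <end>\\t<surface>`` — a concept span;
* ``R<k>\\t<rel-label> Arg1:T<i> Arg2:T<j>`` — a relation;
* ``A<k>\\tNegation T<j>`` — a negation attribute on a lesion span.

Labels are matched case-insensitively on read and written in canonical
spelling (``Lesion``, ``Eye_part``, ``Laterality``, ``Severity``;
``located``, ``laterality-lesion``, ``severity-lesion``). Discontinuous
spans (``0 5;10 15``) are collapsed to their envelope with a warning.
Offsets count Unicode code points; files are read and written as UTF-8.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .schema import (
    RELATION_FOR_ATTRIBUTE,
    AnnotatedDocument,
    Category,
    ConceptMention,
    RelationInstance,
    RelationType,
    SchemaError,
)

logger = logging.getLogger(__name__)


class BratParseError(ValueError):
    """A malformed or schema-violating .ann line; the message names it."""


_CATEGORY_LABELS = {
    Category.LESION: "Lesion",
    Category.EYE_PART: "Eye_part",
    Category.LATERALITY: "Laterality",
    Category.SEVERITY: "Severity",
}
_LABEL_TO_CATEGORY = {v.lower(): k for k, v in _CATEGORY_LABELS.items()}

_RELATION_LABELS = {
    RelationType.LOCATED: "located",
    RelationType.LATERALITY_LESION: "laterality-lesion",
    RelationType.SEVERITY_LESION: "severity-lesion",
}
_LABEL_TO_RELATION = {v.lower(): k for k, v in _RELATION_LABELS.items()}
# tolerate underscore spelling on read
_LABEL_TO_RELATION.update({v.replace("-", "_").lower(): k for k, v in _RELATION_LABELS.items()})


def _parse_t_line(line: str, text: str) -> ConceptMention:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"malformed T line (missing tab): {line!r}")
    tid = parts[0]
    header = parts[1]
    given_surface = parts[2] if len(parts) > 2 else None
    fields = header.split(" ", 1)
    if len(fields) != 2:
        raise BratParseError(f"malformed T line header: {line!r}")
    label, span_str = fields
    category = _LABEL_TO_CATEGORY.get(label.strip().lower())
    if category is None:
        raise BratParseError(f"unknown concept label {label!r} in line: {line!r}")
    fragments = []
    for frag in span_str.split(";"):
        try:
            s, e = frag.split()
            fragments.append((int(s), int(e)))
        except ValueError as exc:
            raise BratParseError(f"bad offsets in line: {line!r}") from exc
    start = min(s for s, _ in fragments)
    end = max(e for _, e in fragments)
    if len(fragments) > 1:
        logger.warning(
            "%s: discontinuous span %s collapsed to envelope (%d, %d)",
            tid, span_str, start, end,
        )
        given_surface = None  # fragment text cannot match the envelope slice
    if not (0 <= start < end <= len(text)):
        raise BratParseError(
            f"offsets ({start}, {end}) outside text of length {len(text)} in line: {line!r}"
        )
    surface = text[start:end]
    if given_surface is not None and given_surface != surface:
        raise BratParseError(
            f"surface {given_surface!r} does not match text slice {surface!r} in line: {line!r}"
        )
    return ConceptMention(id=tid, category=category, start=start, end=end, surface=surface)


def _parse_r_line(line: str, mentions: dict[str, ConceptMention]) -> RelationInstance:
    parts = line.split("\t")
    if len(parts) < 2:
        raise BratParseError(f"malformed R line (missing tab): {line!r}")
    rid = parts[0]
    fields = parts[1].split()
    if len(fields) != 3:
        raise BratParseError(f"malformed R line body: {line!r}")
    label, arg1, arg2 = fields
    rel_type = _LABEL_TO_RELATION.get(label.strip().lower())
    if rel_type is None:
        raise BratParseError(f"unknown relation label {label!r} in line: {line!r}")
    ids = []
    for arg in (arg1, arg2):
        if ":" not in arg:
            raise BratParseError(f"malformed relation argument {arg!r} in line: {line!r}")
        ids.append(arg.split(":", 1)[1])
    for tid in ids:
        if tid not in mentions:
            raise BratParseError(f"relation argument {tid!r} references missing T id in line: {line!r}")
    cats = [mentions[tid].category for tid in ids]
    # attribute-first is the canonical order, but accept lesion-first when
    # the categories disambiguate it
    if cats[0] is not Category.LESION and cats[1] is Category.LESION:
        attribute_id, lesion_id = ids
    elif cats[0] is Category.LESION and cats[1] is not Category.LESION:
        lesion_id, attribute_id = ids
    else:
        raise BratParseError(
            f"relation arguments must be one lesion and one attribute, got "
            f"({cats[0].value}, {cats[1].value}) in line: {line!r}"
        )
    expected = RELATION_FOR_ATTRIBUTE[mentions[attribute_id].category]
    if rel_type is not expected:
        raise BratParseError(
            f"relation type {label!r} does not match attribute category "
            f"{mentions[attribute_id].category.value} in line: {line!r}"
        )
    return RelationInstance(id=rid, rel_type=rel_type, attribute_id=attribute_id, lesion_id=lesion_id)


def parse_document(txt_content: str, ann_content: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Parse a .txt/.ann pair into an :class:`AnnotatedDocument`.

    Every T/R/A line is either consumed or raises :class:`BratParseError`;
    nothing is silently dropped.
    """
    mentions: dict[str, ConceptMention] = {}
    relations: list[RelationInstance] = []
    pending_r: list[str] = []
    pending_a: list[str] = []
    for raw in ann_content.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        kind = line[0]
        if kind == "T":
            m = _parse_t_line(line, txt_content)
            if m.id in mentions:
                raise BratParseError(f"duplicate mention id {m.id!r}")
            mentions[m.id] = m
        elif kind == "R":
            pending_r.append(line)  # resolved after all T lines are known
        elif kind == "A":
            pending_a.append(line)
        else:
            raise BratParseError(f"unsupported annotation line type {kind!r}: {line!r}")
    for line in pending_r:
        relations.append(_parse_r_line(line, mentions))
    for line in pending_a:
        parts = line.split("\t")
        if len(parts) < 2:
            raise BratParseError(f"malformed A line (missing tab): {line!r}")
        fields = parts[1].split()
        if len(fields) != 2:
            raise BratParseError(f"malformed A line body: {line!r}")
        attr_label, target = fields
        if attr_label.strip().lower() != "negation":
            raise BratParseError(f"unknown attribute label {attr_label!r} in line: {line!r}")
        if target not in mentions:
            raise BratParseError(f"negation target {target!r} references missing T id in line: {line!r}")
        if mentions[target].category is not Category.LESION:
            raise BratParseError(
                f"negation attribute on non-lesion mention {target!r} in line: {line!r}"
            )
        mentions[target].negated = True
    doc = AnnotatedDocument(
        doc_id=doc_id, text=txt_content, mentions=list(mentions.values()), relations=relations
    )
    doc.validate()
    return doc


def write_ann(doc: AnnotatedDocument) -> str:
    """Serialize a document's annotations to .ann text.

    The output re-parses to an equivalent document; ids are preserved.
    Raises :class:`SchemaError` if the document violates its invariants.
    """
    doc.validate()
    lines: list[str] = []
    for m in doc.mentions:
        label = _CATEGORY_LABELS[m.category]
        lines.append(f"{m.id}\t{label} {m.start} {m.end}\t{m.surface}")
    for r in doc.relations:
        label = _RELATION_LABELS[r.rel_type]
        lines.append(f"{r.id}\t{label} Arg1:{r.attribute_id} Arg2:{r.lesion_id}")
    k = 1
    for m in doc.mentions:
        if m.negated:
            lines.append(f"A{k}\tNegation {m.id}")
            k += 1
    return "\n".join(lines) + ("\n" if lines else "")


def read_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    """Read all .txt/.ann pairs in a directory, paired by basename.

    A .txt without a sibling .ann yields a document with no annotations.
    """
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        ann_path = txt_path.with_suffix(".ann")
        text = txt_path.read_text(encoding="utf-8")
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        docs.append(parse_document(text, ann, doc_id=txt_path.stem))
    return docs


def write_corpus(docs: list[AnnotatedDocument], directory: str | Path) -> None:
    """Write each document as a .txt/.ann pair named by its doc_id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(write_ann(doc), encoding="utf-8")
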