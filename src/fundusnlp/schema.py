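"""Core annotation types for the diabetic-retinopathy report schema.

The schema has four concept categories — lesions and three attribute
categories (eye part, laterality, severity) — and three relation types,
each linking one attribute category to a lesion:

    eye_part   --located-->           lesion
    laterality --laterality_lesion--> lesion
    severity   --severity_lesion-->   lesion

Negation is a boolean attribute carried by lesion mentions only.
Character offsets are 0-based, end-exclusive, counted in Unicode code
points (the brat convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum


class SchemaError(ValueError):
    """An annotation object violates the schema invariants."""


class Category(str, Enum):
    LESION = "lesion"
    EYE_PART = "eye_part"
    LATERALITY = "laterality"
    SEVERITY = "severity"


class RelationType(str, Enum):
    LOCATED = "located"
    LATERALITY_LESION = "laterality_lesion"
    SEVERITY_LESION = "severity_lesion"


#: The relation type is a function of the attribute's category.
RELATION_FOR_ATTRIBUTE: dict[Category, RelationType] = {
    Category.EYE_PART: RelationType.LOCATED,
    Category.LATERALITY: RelationType.LATERALITY_LESION,
    Category.SEVERITY: RelationType.SEVERITY_LESION,
}

ATTRIBUTE_CATEGORIES = (Category.EYE_PART, Category.LATERALITY, Category.SEVERITY)


@dataclass
class ConceptMention:
    """A typed character span in a report.

    ``negated`` is meaningful only for lesions; the validator rejects a
    true flag on any other category.
    """

    id: str
    category: Category
    start: int
    end: int
    surface: str
    negated: bool = False

    def overlaps(self, other: "ConceptMention") -> bool:
        return self.start < other.end and other.start < self.end

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class RelationInstance:
    """A typed directed link from an attribute mention to a lesion mention."""

    id: str
    rel_type: RelationType
    attribute_id: str
    lesion_id: str


@dataclass
class AnnotatedDocument:
    """Report text plus its concept mentions and relations.

    The unit of I/O, prediction, and scoring.
    """

    doc_id: str
    text: str
    mentions: list[ConceptMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    def mention_by_id(self, mid: str) -> ConceptMention:
        for m in self.mentions:
            if m.id == mid:
                return m
        raise KeyError(f"no mention with id {mid!r} in document {self.doc_id!r}")

    def validate(self) -> None:
        """Raise :class:`SchemaError` on any invariant violation."""
        n = len(self.text)
        ids: set[str] = set()
        keys: set[tuple[int, int, Category]] = set()
        for m in self.mentions:
            if m.id in ids:
                raise SchemaError(f"{self.doc_id}: duplicate mention id {m.id!r}")
            ids.add(m.id)
            if not (0 <= m.start < m.end <= n):
                raise SchemaError(
                    f"{self.doc_id}/{m.id}: span ({m.start}, {m.end}) outside text of length {n}"
                )
            if self.text[m.start : m.end] != m.surface:
                raise SchemaError(
                    f"{self.doc_id}/{m.id}: surface {m.surface!r} does not equal text slice "
                    f"{self.text[m.start:m.end]!r}"
                )
            if m.negated and m.category is not Category.LESION:
                raise SchemaError(
                    f"{self.doc_id}/{m.id}: negated=True on non-lesion category {m.category.value}"
                )
            key = (m.start, m.end, m.category)
            if key in keys:
                raise SchemaError(f"{self.doc_id}/{m.id}: duplicate mention at {key}")
            keys.add(key)
        rids: set[str] = set()
        by_id = {m.id: m for m in self.mentions}
        for r in self.relations:
            if r.id in rids:
                raise SchemaError(f"{self.doc_id}: duplicate relation id {r.id!r}")
            rids.add(r.id)
            if r.lesion_id not in by_id or r.attribute_id not in by_id:
                raise SchemaError(
                    f"{self.doc_id}/{r.id}: argument ids ({r.attribute_id}, {r.lesion_id}) "
                    "do not resolve to mentions"
                )
            lesion = by_id[r.lesion_id]
            attr = by_id[r.attribute_id]
            if lesion.category is not Category.LESION:
                raise SchemaError(
                    f"{self.doc_id}/{r.id}: lesion argument {r.lesion_id} has category "
                    f"{lesion.category.value}"
                )
            if attr.category is Category.LESION:
                raise SchemaError(
                    f"{self.doc_id}/{r.id}: attribute argument {r.attribute_id} is a lesion"
                )
            expected = RELATION_FOR_ATTRIBUTE[attr.category]
            if r.rel_type is not expected:
                raise SchemaError(
                    f"{self.doc_id}/{r.id}: relation type {r.rel_type.value} does not match "
                    f"attribute category {attr.category.value} (expected {expected.value})"
                )

    def copy_without_annotations(self) -> "AnnotatedDocument":
        return AnnotatedDocument(doc_id=self.doc_id, text=self.text)


def copy_mention(m: ConceptMention, **changes) -> ConceptMention:
    return replace(m, **changes)
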