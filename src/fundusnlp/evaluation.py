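"""Scoring protocol: strict/lenient P/R/F1, micro averaging, agreement.

Strict span matching requires identical boundaries and category; lenient
matching requires at least one shared character and the same category.
Matching is one-to-one — each gold mention consumes at most one
prediction — greedy in gold offset order with an earliest-offset
tie-break among candidate predictions. A predicted relation is correct
iff its type matches and both arguments match gold arguments under the
active mode (both arguments lenient in lenient mode).

Micro averages pool tp / n_pred / n_gold across categories before
computing metrics; they are not means of per-category scores. When a
denominator is zero the metric is reported as 0.0 and the row carries a
zero-support flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .schema import AnnotatedDocument, Category, ConceptMention, RelationType


class EvalError(ValueError):
    pass


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise EvalError(f"{name} must lie in [0, 1], got {v}")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class MatchCounts:
    tp: int = 0
    n_pred: int = 0
    n_gold: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(
            self.tp + other.tp, self.n_pred + other.n_pred, self.n_gold + other.n_gold
        )

    @property
    def zero_support(self) -> bool:
        return self.n_pred == 0 or self.n_gold == 0

    @property
    def precision(self) -> float:
        return self.tp / self.n_pred if self.n_pred else 0.0

    @property
    def recall(self) -> float:
        return self.tp / self.n_gold if self.n_gold else 0.0

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)


@dataclass
class EvalRow:
    name: str
    strict: MatchCounts = field(default_factory=MatchCounts)
    lenient: MatchCounts = field(default_factory=MatchCounts)


@dataclass
class EvalReport:
    """Per-category rows plus a pooled micro row, both match modes."""

    rows: dict[str, EvalRow]
    micro: EvalRow

    def __post_init__(self) -> None:
        for row in list(self.rows.values()) + [self.micro]:
            if row.lenient.tp < row.strict.tp:
                raise EvalError(f"row {row.name}: lenient tp < strict tp")
        for mode in ("strict", "lenient"):
            for attr in ("tp", "n_pred", "n_gold"):
                total = sum(getattr(getattr(r, mode), attr) for r in self.rows.values())
                if total != getattr(getattr(self.micro, mode), attr):
                    raise EvalError(f"micro {mode}.{attr} does not equal category sum")

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in list(self.rows.values()) + [self.micro]:
            records.append(
                {
                    "category": row.name,
                    "strict_precision": row.strict.precision,
                    "strict_recall": row.strict.recall,
                    "strict_f1": row.strict.f1,
                    "lenient_precision": row.lenient.precision,
                    "lenient_recall": row.lenient.recall,
                    "lenient_f1": row.lenient.f1,
                    "n_gold": row.strict.n_gold,
                    "n_pred": row.strict.n_pred,
                }
            )
        return pd.DataFrame.from_records(records).set_index("category")


def _spans_match(p: ConceptMention, g: ConceptMention, mode: str) -> bool:
    if p.category is not g.category:
        return False
    if mode == "strict":
        return p.start == g.start and p.end == g.end
    if mode == "lenient":
        return p.start < g.end and g.start < p.end
    raise EvalError(f"unknown match mode {mode!r}")


def match_concepts(
    pred: list[ConceptMention], gold: list[ConceptMention], mode: str
) -> MatchCounts:
    """One-to-one greedy matching; see module docstring for the policy."""
    used: set[int] = set()
    tp = 0
    for g in sorted(gold, key=lambda m: (m.start, m.end)):
        candidates = [
            (p.start, p.end, i)
            for i, p in enumerate(pred)
            if i not in used and _spans_match(p, g, mode)
        ]
        if candidates:
            used.add(min(candidates)[2])
            tp += 1
    return MatchCounts(tp=tp, n_pred=len(pred), n_gold=len(gold))


def _aligned_pairs(
    pred_docs: list[AnnotatedDocument], gold_docs: list[AnnotatedDocument]
) -> list[tuple[AnnotatedDocument, AnnotatedDocument]]:
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if len(pred_by_id) != len(pred_docs) or set(pred_by_id) != {d.doc_id for d in gold_docs}:
        raise EvalError("pred and gold corpora are not aligned by doc_id")
    return [(pred_by_id[g.doc_id], g) for g in gold_docs]


def evaluate_concepts(
    pred_docs: list[AnnotatedDocument], gold_docs: list[AnnotatedDocument]
) -> EvalReport:
    """Per-category and micro-averaged concept scores in both modes."""
    pairs = _aligned_pairs(pred_docs, gold_docs)
    rows = {c.value: EvalRow(c.value) for c in Category}
    for pred, gold in pairs:
        for cat in Category:
            p = [m for m in pred.mentions if m.category is cat]
            g = [m for m in gold.mentions if m.category is cat]
            row = rows[cat.value]
            row.strict = row.strict + match_concepts(p, g, "strict")
            row.lenient = row.lenient + match_concepts(p, g, "lenient")
    micro = EvalRow(
        "micro",
        strict=sum((r.strict for r in rows.values()), MatchCounts()),
        lenient=sum((r.lenient for r in rows.values()), MatchCounts()),
    )
    return EvalReport(rows=rows, micro=micro)


def _relation_tuples(doc: AnnotatedDocument):
    by_id = {m.id: m for m in doc.mentions}
    return [
        (r.rel_type, by_id[r.attribute_id], by_id[r.lesion_id]) for r in doc.relations
    ]


def _match_relations(pred, gold, mode: str) -> MatchCounts:
    used: set[int] = set()
    tp = 0
    for g_type, g_attr, g_lesion in sorted(
        gold, key=lambda t: (t[1].start, t[2].start)
    ):
        candidates = []
        for i, (p_type, p_attr, p_lesion) in enumerate(pred):
            if i in used or p_type is not g_type:
                continue
            if _spans_match(p_attr, g_attr, mode) and _spans_match(p_lesion, g_lesion, mode):
                candidates.append((p_attr.start, p_lesion.start, i))
        if candidates:
            used.add(min(candidates)[2])
            tp += 1
    return MatchCounts(tp=tp, n_pred=len(pred), n_gold=len(gold))


def evaluate_relations(
    pred_docs: list[AnnotatedDocument],
    gold_docs: list[AnnotatedDocument],
    setting: str = "e2e",
) -> EvalReport:
    """Relation scores per type and micro, both modes.

    In the gold-concept setting the strict and lenient scores must be
    identical (arguments are the gold spans themselves); the report
    construction enforces that equality.
    """
    if setting not in ("gold", "e2e"):
        raise EvalError(f"unknown setting {setting!r}")
    pairs = _aligned_pairs(pred_docs, gold_docs)
    rows = {t.value: EvalRow(t.value) for t in RelationType}
    for pred, gold in pairs:
        p_all = _relation_tuples(pred)
        g_all = _relation_tuples(gold)
        for rel_type in RelationType:
            p = [t for t in p_all if t[0] is rel_type]
            g = [t for t in g_all if t[0] is rel_type]
            row = rows[rel_type.value]
            row.strict = row.strict + _match_relations(p, g, "strict")
            row.lenient = row.lenient + _match_relations(p, g, "lenient")
    micro = EvalRow(
        "micro",
        strict=sum((r.strict for r in rows.values()), MatchCounts()),
        lenient=sum((r.lenient for r in rows.values()), MatchCounts()),
    )
    report = EvalReport(rows=rows, micro=micro)
    if setting == "gold":
        for row in list(rows.values()) + [micro]:
            if row.strict != row.lenient:
                raise EvalError(
                    f"gold-concept setting requires strict == lenient, violated in row {row.name}"
                )
    return report


def cohen_kappa_tokens(
    labels_a: list[list[str]], labels_b: list[list[str]]
) -> float:
    """Token-level Cohen's kappa over aligned BIO label sequences."""
    if len(labels_a) != len(labels_b):
        raise EvalError("annotators labeled different numbers of sequences")
    flat_a: list[str] = []
    flat_b: list[str] = []
    for a, b in zip(labels_a, labels_b):
        if len(a) != len(b):
            raise EvalError("label sequences have different lengths (tokenizations differ)")
        flat_a.extend(a)
        flat_b.extend(b)
    if not flat_a:
        raise EvalError("no tokens to compare")
    if flat_a == flat_b:
        return 1.0  # p_o = 1; covers the degenerate p_e = 1 case
    return float(cohen_kappa_score(flat_a, flat_b))


def concept_agreement_f1(
    ann_a: list[AnnotatedDocument], ann_b: list[AnnotatedDocument]
) -> float:
    """Concept-level agreement: lenient micro F1 with A as reference."""
    shared = {d.doc_id for d in ann_a} & {d.doc_id for d in ann_b}
    if not shared:
        raise EvalError("annotators share no documents")
    a = [d for d in ann_a if d.doc_id in shared]
    b = [d for d in ann_b if d.doc_id in shared]
    return evaluate_concepts(b, a).micro.lenient.f1
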