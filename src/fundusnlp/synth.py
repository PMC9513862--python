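"""Synthetic brat-annotated fundus reports.

Real fundus-report corpora are protected health information; this module
generates structurally faithful stand-ins so that every downstream stage
(concept tagging, negation, relation classification, evaluation) can be
trained and scored without any private data. Documents are built from a
template grammar of clinical-style sentence frames:

    [<cue> ][<severity> ]<lesion>[ and <lesion>][ in the <eye part>][ of the <laterality>].

Attributes attach to the nearest lesion: a severity modifier to the
lesion it directly precedes, an eye part or laterality to the closest
preceding lesion. Negated sentences always contain a single lesion, so
the gold negation flag is exactly "a cue opens this sentence". Every
relation links mentions inside one sentence, by construction — mirroring
the dominant same-sentence pattern of real reports.

Default rates follow the shape of an annotated corpus of 536 reports
from a retinopathy clinic: roughly 24% of lesion mentions negated, and
per-lesion attribute rates of 0.54 (laterality), 0.25 (severity), and
0.02 (eye part). The negation-cue list deliberately contains phrases
absent from the default NegEx-style lexicon ("free of", "absence of"),
so that trigger mining has something real to discover.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .schema import (
    RELATION_FOR_ATTRIBUTE,
    AnnotatedDocument,
    Category,
    ConceptMention,
    RelationInstance,
)

DEFAULT_VOCABULARIES: dict[str, list[str]] = {
    "lesion": [
        "hemorrhage",
        "microaneurysm",
        "exudate",
        "cotton wool spot",
        "neovascularization",
        "macular edema",
    ],
    "eye_part": ["foveal", "macula", "retina", "optic disc"],
    "laterality": ["right eye", "left eye", "both eyes", "OD", "OS", "OU"],
    "severity": ["mild", "moderate", "severe"],
}

#: "free of" and "absence of" are intentionally outside the default
#: detection lexicon; trigger mining should recover them from gold flags.
DEFAULT_NEGATION_CUES = [
    "no",
    "without",
    "no evidence of",
    "negative for",
    "free of",
    "absence of",
]

_DISTRACTORS = [
    "visual acuity is stable.",
    "the patient will return in 3 months.",
    "dilated fundus examination was performed today.",
    "media are clear.",
    "follow up as scheduled.",
    "intraocular pressure within normal limits.",
]


class ConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults emulate the reference corpus shape."""

    n_docs: int = 536
    seed: int = 13
    sentences_per_doc: tuple[int, int] = (3, 8)
    negation_rate: float = 0.24
    attribute_rates: dict[str, float] = field(
        default_factory=lambda: {"laterality": 0.54, "severity": 0.25, "eye_part": 0.02}
    )
    vocabularies: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_VOCABULARIES.items()}
    )
    negation_cues: list[str] = field(default_factory=lambda: list(DEFAULT_NEGATION_CUES))
    distractor_rate: float = 0.25
    two_lesion_rate: float = 0.25

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ConfigError("n_docs must be >= 1")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ConfigError("sentences_per_doc must be a range with 1 <= lo <= hi")
        probs = [self.negation_rate, self.distractor_rate, self.two_lesion_rate,
                 *self.attribute_rates.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all rates must lie in [0, 1]")
        for name, vocab in self.vocabularies.items():
            if not vocab:
                raise ConfigError(f"empty vocabulary for {name!r}")
        if not self.negation_cues:
            raise ConfigError("negation cue list must be non-empty")


class _DocBuilder:
    """Accumulates text and mentions with exact character offsets."""

    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0
        self.mentions: list[ConceptMention] = []
        self.relations: list[RelationInstance] = []

    def emit(self, fragment: str) -> None:
        self.parts.append(fragment)
        self.length += len(fragment)

    def emit_mention(self, surface: str, category: Category, negated: bool = False) -> ConceptMention:
        m = ConceptMention(
            id=f"T{len(self.mentions) + 1}",
            category=category,
            start=self.length,
            end=self.length + len(surface),
            surface=surface,
            negated=negated,
        )
        self.emit(surface)
        self.mentions.append(m)
        return m

    def link(self, attribute: ConceptMention, lesion: ConceptMention) -> None:
        self.relations.append(
            RelationInstance(
                id=f"R{len(self.relations) + 1}",
                rel_type=RELATION_FOR_ATTRIBUTE[attribute.category],
                attribute_id=attribute.id,
                lesion_id=lesion.id,
            )
        )

    def build(self) -> AnnotatedDocument:
        doc = AnnotatedDocument(
            doc_id=self.doc_id,
            text="".join(self.parts),
            mentions=self.mentions,
            relations=self.relations,
        )
        doc.validate()
        return doc


def _lesion_sentence(b: _DocBuilder, cfg: SynthConfig, rng: random.Random) -> None:
    vocab = cfg.vocabularies
    negated = rng.random() < cfg.negation_rate
    # negated frames stay single-lesion so the cue's scope is unambiguous
    two = (not negated) and rng.random() < cfg.two_lesion_rate and len(vocab["lesion"]) >= 2
    with_severity = rng.random() < cfg.attribute_rates.get("severity", 0.0)
    with_eye_part = rng.random() < cfg.attribute_rates.get("eye_part", 0.0)
    with_laterality = rng.random() < cfg.attribute_rates.get("laterality", 0.0)

    if negated:
        b.emit(rng.choice(cfg.negation_cues) + " ")
    severity = None
    if with_severity:
        severity = b.emit_mention(rng.choice(vocab["severity"]), Category.SEVERITY)
        b.emit(" ")
    first = b.emit_mention(rng.choice(vocab["lesion"]), Category.LESION, negated=negated)
    nearest = first
    if two:
        b.emit(" and ")
        second_surface = rng.choice([s for s in vocab["lesion"]
                                     if s != first.surface] or vocab["lesion"])
        nearest = b.emit_mention(second_surface, Category.LESION)
    if severity is not None:
        b.link(severity, first)
    if with_eye_part:
        b.emit(" in the ")
        ep = b.emit_mention(rng.choice(vocab["eye_part"]), Category.EYE_PART)
        b.link(ep, nearest)
    if with_laterality:
        b.emit(" of the ")
        lat = b.emit_mention(rng.choice(vocab["laterality"]), Category.LATERALITY)
        b.link(lat, nearest)
    b.emit(".")


def generate_document(doc_id: str, cfg: SynthConfig, rng: random.Random) -> AnnotatedDocument:
    b = _DocBuilder(doc_id)
    lo, hi = cfg.sentences_per_doc
    n_sent = rng.randint(lo, hi)
    for i in range(n_sent):
        if i > 0:
            b.emit("\n" if rng.random() < 0.3 else " ")
        if rng.random() < cfg.distractor_rate:
            b.emit(rng.choice(_DISTRACTORS))
        else:
            _lesion_sentence(b, cfg, rng)
    return b.build()


def generate_corpus(cfg: SynthConfig) -> list[AnnotatedDocument]:
    """Deterministic corpus from a single seeded stream."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    width = max(4, len(str(cfg.n_docs)))
    return [
        generate_document(f"doc_{i:0{width}d}", cfg, rng) for i in range(cfg.n_docs)
    ]


def split_corpus(
    docs: list[AnnotatedDocument], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Document-level random partition; train gets round(n * fraction)."""
    if len(docs) < 2:
        raise ConfigError("need at least 2 documents to split")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError("train_fraction must lie strictly between 0 and 1")
    order = list(range(len(docs)))
    random.Random(seed).shuffle(order)
    n_train = round(len(docs) * train_fraction)
    n_train = min(max(n_train, 1), len(docs) - 1)  # both halves non-empty
    train = [docs[i] for i in sorted(order[:n_train])]
    test = [docs[i] for i in sorted(order[n_train:])]
    return train, test
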