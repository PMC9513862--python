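import copy
import random

import pytest

from fundusnlp import (
    cohen_kappa_tokens,
    concept_agreement_f1,
    evaluate_concepts,
    evaluate_relations,
    f1,
    match_concepts,
)
from fundusnlp.evaluation import EvalError, MatchCounts
from fundusnlp.schema import AnnotatedDocument, Category, ConceptMention


class TestF1:
    @pytest.mark.parametrize(
        "p, r, expected",
        [
            (0.9486, 0.9520, 0.9503),
            (1.0, 1.0, 1.0),
            (0.9199, 0.9437, 0.9316),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_reported_values(self, p, r, expected):
        assert round(f1(p, r), 4) == pytest.approx(expected)

    @pytest.mark.parametrize("v", [0.0, 0.3, 0.75, 1.0])
    def test_fixed_point_when_equal(self, v):
        assert f1(v, v) == pytest.approx(v)

    @pytest.mark.parametrize("p, r", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, p, r):
        with pytest.raises(EvalError):
            f1(p, r)


def _m(cat, start, end, text):
    return ConceptMention(f"T{start}_{end}_{cat.value}", cat, start, end, text[start:end])


def _brute_force_max_matching(pred, gold, match_fn):
    """Exhaustive one-to-one assignment maximizing matched pairs."""

    def rec(gi, used):
        if gi == len(gold):
            return 0
        best = rec(gi + 1, used)  # leave this gold unmatched
        for i, p in enumerate(pred):
            if i not in used and match_fn(p, gold[gi]):
                best = max(best, 1 + rec(gi + 1, used | {i}))
        return best

    return rec(0, frozenset())


class TestMatchConcepts:
    text = "x" * 40

    def test_identical_sets(self):
        gold = [_m(Category.LESION, 0, 5, self.text), _m(Category.SEVERITY, 6, 10, self.text)]
        counts = match_concepts(list(gold), gold, "strict")
        assert (counts.tp, counts.n_pred, counts.n_gold) == (2, 2, 2)

    def test_boundary_off_strict_vs_lenient(self):
        gold = [_m(Category.LESION, 5, 15, self.text)]
        pred = [_m(Category.LESION, 5, 14, self.text)]
        assert match_concepts(pred, gold, "strict").tp == 0
        assert match_concepts(pred, gold, "lenient").tp == 1

    def test_category_mismatch_never_matches(self):
        gold = [_m(Category.LESION, 5, 15, self.text)]
        pred = [_m(Category.EYE_PART, 5, 15, self.text)]
        assert match_concepts(pred, gold, "strict").tp == 0
        assert match_concepts(pred, gold, "lenient").tp == 0

    def test_split_prediction_against_exhaustive_oracle(self):
        """One gold mention predicted as two pieces: the one-to-one rule
        allows only one credit; counts equal a brute-force assignment."""
        text = self.text
        gold = [
            _m(Category.LESION, 0, 10, text),
            _m(Category.LESION, 12, 20, text),
            _m(Category.SEVERITY, 22, 26, text),
        ]
        pred = [
            _m(Category.LESION, 0, 4, text),
            _m(Category.LESION, 5, 10, text),  # split of gold[0]
            _m(Category.LESION, 12, 20, text),
            _m(Category.SEVERITY, 22, 26, text),
        ]
        from fundusnlp.evaluation import _spans_match

        for mode in ("strict", "lenient"):
            expected = _brute_force_max_matching(
                pred, gold, lambda p, g, mode=mode: _spans_match(p, g, mode)
            )
            assert match_concepts(pred, gold, mode).tp == expected

    def test_random_fixtures_against_oracle(self):
        """Greedy one-to-one matching equals exhaustive assignment on
        random fixtures of up to 8 mentions."""
        from fundusnlp.evaluation import _spans_match

        rng = random.Random(4)
        text = "x" * 60
        for _ in range(200):
            def spans(n):
                out = []
                cursor = 0
                for _ in range(n):
                    s = cursor + rng.randint(0, 2)
                    e = s + rng.randint(1, 4)
                    out.append(_m(rng.choice([Category.LESION, Category.SEVERITY]), s, e, text))
                    cursor = e + rng.randint(0, 1)
                return out

            gold, pred = spans(rng.randint(0, 4)), spans(rng.randint(0, 4))
            for mode in ("strict", "lenient"):
                expected = _brute_force_max_matching(
                    pred, gold, lambda p, g, mode=mode: _spans_match(p, g, mode)
                )
                assert match_concepts(pred, gold, mode).tp == expected


class TestEvaluateConcepts:
    def test_identity_scores_one(self, small_corpus):
        report = evaluate_concepts(small_corpus[:20], small_corpus[:20])
        assert report.micro.strict.f1 == 1.0
        assert report.micro.lenient.f1 == 1.0

    def test_no_predictions(self, small_corpus):
        gold = small_corpus[:5]
        pred = [d.copy_without_annotations() for d in gold]
        report = evaluate_concepts(pred, gold)
        assert report.micro.strict.precision == 0.0
        assert report.micro.strict.recall == 0.0
        assert report.micro.strict.zero_support

    def test_unaligned_corpora_rejected(self, small_corpus):
        with pytest.raises(EvalError):
            evaluate_concepts(small_corpus[:3], small_corpus[3:6])

    def test_micro_is_pooled_not_mean_of_categories(self):
        """Hand-built 2-category fixture where pooling and averaging differ:
        lesion (1 of 3 found, all preds correct) F1=0.5, severity F1=1.0;
        mean would be 0.75 but pooled counts give 2/3."""
        text = "abcdefgh"
        gold = AnnotatedDocument(
            "d", text,
            [
                _m(Category.LESION, 0, 1, text),
                _m(Category.LESION, 2, 3, text),
                _m(Category.LESION, 4, 5, text),
                _m(Category.SEVERITY, 6, 7, text),
            ],
        )
        pred = AnnotatedDocument(
            "d", text,
            [_m(Category.LESION, 0, 1, text), _m(Category.SEVERITY, 6, 7, text)],
        )
        report = evaluate_concepts([pred], [gold])
        assert report.rows["lesion"].strict.f1 == pytest.approx(0.5)
        assert report.rows["severity"].strict.f1 == pytest.approx(1.0)
        assert report.micro.strict.f1 == pytest.approx(2 / 3)
        assert report.micro.strict.f1 != pytest.approx(0.75)

    def test_micro_counts_are_category_sums(self, small_corpus):
        report = evaluate_concepts(small_corpus[:30], small_corpus[:30])
        for mode in ("strict", "lenient"):
            for attr in ("tp", "n_pred", "n_gold"):
                assert getattr(getattr(report.micro, mode), attr) == sum(
                    getattr(getattr(r, mode), attr) for r in report.rows.values()
                )


def _perturb(doc, rng):
    """Shift some mention boundaries by one character; drop ~10%."""
    out = copy.deepcopy(doc)
    kept = []
    for m in out.mentions:
        if rng.random() < 0.1:
            continue
        if rng.random() < 0.4 and m.end + 1 <= len(out.text):
            m.end += 1
        m.surface = out.text[m.start:m.end]
        kept.append(m)
    kept_ids = {m.id for m in kept}
    out.mentions = kept
    out.relations = [
        r for r in out.relations
        if r.attribute_id in kept_ids and r.lesion_id in kept_ids
    ]
    return out


class TestEvaluateRelations:
    def test_gold_setting_identity(self, small_corpus):
        report = evaluate_relations(small_corpus[:20], small_corpus[:20], setting="gold")
        assert report.micro.strict.f1 == 1.0
        assert report.micro.strict == report.micro.lenient

    def test_boundary_off_counts_only_lenient(self, simple_doc):
        pred = copy.deepcopy(simple_doc)
        lesion = pred.mention_by_id("T3")
        lesion.end -= 1
        lesion.surface = pred.text[lesion.start:lesion.end]
        report = evaluate_relations([pred], [simple_doc], setting="e2e")
        assert report.micro.strict.tp == 0
        assert report.micro.lenient.tp == 3

    def test_fixture_against_exhaustive_oracle(self, small_corpus):
        """Perturbed predictions over >= 10 relations: micro counts equal a
        brute-force maximum assignment per document."""
        from fundusnlp.evaluation import _relation_tuples, _spans_match

        rng = random.Random(11)
        gold_docs = [d for d in small_corpus if len(d.relations) >= 3][:4]
        pred_docs = [_perturb(d, rng) for d in gold_docs]
        assert sum(len(d.relations) for d in gold_docs) >= 10
        report = evaluate_relations(pred_docs, gold_docs, setting="e2e")
        for mode in ("strict", "lenient"):
            expected_tp = 0
            for p_doc, g_doc in zip(pred_docs, gold_docs):
                def rel_match(p, g, mode=mode):
                    return (
                        p[0] is g[0]
                        and _spans_match(p[1], g[1], mode)
                        and _spans_match(p[2], g[2], mode)
                    )

                expected_tp += _brute_force_max_matching(
                    _relation_tuples(p_doc), _relation_tuples(g_doc), rel_match
                )
            assert getattr(report.micro, mode).tp == expected_tp

    def test_lenient_dominates_strict_everywhere(self, small_corpus):
        rng = random.Random(12)
        gold = small_corpus[:30]
        pred = [_perturb(d, rng) for d in gold]
        for report in (
            evaluate_concepts(pred, gold),
            evaluate_relations(pred, gold, setting="e2e"),
        ):
            for row in list(report.rows.values()) + [report.micro]:
                assert row.lenient.tp >= row.strict.tp
                assert row.lenient.f1 >= row.strict.f1


class TestCohenKappa:
    def test_perfect_agreement(self):
        labels = [["O", "B-Lesion", "I-Lesion"], ["O", "O"]]
        assert cohen_kappa_tokens(labels, labels) == 1.0

    def test_hand_computed_contingency(self):
        """a=20 (both X), b=5, c=10, d=15: po=0.7, pe=0.5, kappa=0.4."""
        a = ["X"] * 20 + ["X"] * 5 + ["Y"] * 10 + ["Y"] * 15
        b = ["X"] * 20 + ["Y"] * 5 + ["X"] * 10 + ["Y"] * 15
        assert cohen_kappa_tokens([a], [b]) == pytest.approx(0.4)

    def test_independent_labels_near_zero(self):
        rng = random.Random(3)
        a = [rng.choice("XY") for _ in range(20000)]
        b = [rng.choice("XY") for _ in range(20000)]
        assert abs(cohen_kappa_tokens([a], [b])) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvalError):
            cohen_kappa_tokens([["O", "O"]], [["O"]])


class TestConceptAgreement:
    def test_identical_annotations(self, small_corpus):
        assert concept_agreement_f1(small_corpus[:5], small_corpus[:5]) == 1.0

    def test_disjoint_annotations(self):
        text = "abcdef"
        a = [AnnotatedDocument("d", text, [_m(Category.LESION, 0, 2, text)])]
        b = [AnnotatedDocument("d", text, [_m(Category.LESION, 3, 5, text)])]
        assert concept_agreement_f1(a, b) == 0.0

    def test_no_shared_documents_rejected(self, small_corpus):
        with pytest.raises(EvalError):
            concept_agreement_f1(small_corpus[:2], small_corpus[2:4])

    def test_swap_symmetry_on_fixture(self, small_corpus):
        rng = random.Random(9)
        a = small_corpus[:5]
        b = [_perturb(d, rng) for d in a]
        assert concept_agreement_f1(a, b) == pytest.approx(concept_agreement_f1(b, a))
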