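"""The ten sub-scores: worked ratios, edge policies and monotonicity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ontosemscore import subscores as ss
from ontosemscore.errors import (
    ConfigurationError,
    InternalConsistencyError,
    ScoreValidationError,
    UndefinedScoreError,
)
from ontosemscore.lexicon import TermSenseStats, WordSenseLexicon, term_sense_stats
from ontosemscore.ontology_model import ElementCounts, Term, Violation, ViolationReport


def make_report(violating: int, total: int) -> ViolationReport:
    return ViolationReport(
        total_axioms=total,
        violations=tuple(
            Violation(axiom_id=f"ax{i}", rule="undeclared-entity-reference", message="")
            for i in range(violating)
        ),
    )


def make_terms(*labels):
    return [
        Term(surface=l, normalized=(l,), source_entity_kind="class",
             provenance="label-annotation")
        for l in labels
    ]


def make_stats(*senses):
    terms = make_terms(*[f"token{i}" for i in range(len(senses))])
    return [TermSenseStats(term=t, sense_count=s) for t, s in zip(terms, senses)]


class TestSyntactic:
    @pytest.mark.parametrize(
        "violating,total,expected",
        [(0, 100, 1.0), (9, 100, 0.91), (100, 100, 0.0), (0, 0, 1.0)],
    )
    def test_lawfulness(self, violating, total, expected):
        assert ss.lawfulness(make_report(violating, total)) == pytest.approx(expected)

    def test_lawfulness_internal_consistency(self):
        with pytest.raises(InternalConsistencyError):
            make_report(violating=3, total=2)

    @pytest.mark.parametrize(
        "used,size,expected", [(0, 20, 0.0), (20, 20, 1.0), (3, 20, 0.15)]
    )
    def test_richness(self, used, size, expected):
        assert ss.richness(used, size) == pytest.approx(expected)

    def test_richness_empty_inventory(self):
        with pytest.raises(ConfigurationError):
            ss.richness(0, 0)

    @given(
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=1, max_value=50),
        st.integers(min_value=2, max_value=5),
    )
    def test_lawfulness_scale_invariance(self, violating, total, factor):
        if violating > total:
            violating, total = total, violating
        assert ss.lawfulness(make_report(violating, total)) == pytest.approx(
            ss.lawfulness(make_report(violating * factor, total * factor))
        )

    @given(st.integers(min_value=0, max_value=99), st.integers(min_value=1, max_value=100))
    def test_one_more_violation_never_raises_lawfulness(self, violating, total):
        if violating + 1 > total:
            total = violating + 1
        assert ss.lawfulness(make_report(violating + 1, total)) <= ss.lawfulness(
            make_report(violating, total)
        )

    @given(st.integers(min_value=0, max_value=19))
    def test_one_more_construct_never_lowers_richness(self, used):
        assert ss.richness(used + 1, 20) >= ss.richness(used, 20)


class TestSemantic:
    def test_interpretability_fraction(self):
        assert ss.interpretability(make_stats(1, 3, 0)) == pytest.approx(2 / 3)
        assert ss.interpretability(make_stats(1, 1, 1)) == 1.0

    def test_interpretability_empty_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            ss.interpretability([])

    def test_interpretability_matches_brute_force(self, mini_lexicon):
        lemmas = sorted(mini_lexicon.entries)[:30]
        stats = [
            term_sense_stats(t, mini_lexicon)
            for t in make_terms(*lemmas, "zzunknown", "zzother")
        ]
        brute = sum(1 for s in stats if s.sense_count >= 1) / len(stats)
        assert ss.interpretability(stats) == pytest.approx(brute)

    def test_consistency_duplicates(self):
        terms = make_terms("aspirin", "ibuprofen", "aspirin")
        assert ss.consistency(terms) == pytest.approx(0.5)  # T=3, U=2

    def test_consistency_all_unique(self):
        assert ss.consistency(make_terms("a1", "b2", "c3")) == 1.0

    def test_consistency_heavy_duplication_goes_negative(self):
        terms = make_terms(*(["x"] * 3 + ["y"] * 3))  # T = 3U
        assert ss.consistency(terms) == pytest.approx(-1.0)

    def test_consistency_alternative_formula(self):
        terms = make_terms("aspirin", "ibuprofen", "aspirin")
        assert ss.consistency(terms, formula="duplicate-fraction") == pytest.approx(2 / 3)

    def test_consistency_empty_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            ss.consistency([])

    @given(st.lists(st.sampled_from("abcde"), min_size=1, max_size=30))
    def test_adding_duplicate_never_raises_consistency(self, labels):
        terms = make_terms(*labels)
        duplicated = make_terms(*labels, labels[0])
        assert ss.consistency(duplicated) <= ss.consistency(terms) + 1e-12

    def test_clarity_monosemous(self):
        assert ss.clarity(make_stats(1, 1, 1)) == 1.0

    def test_clarity_hand_sum(self):
        assert ss.clarity(make_stats(1, 1, 4)) == pytest.approx(0.5)  # 3/6

    def test_clarity_high_polysemy(self):
        # mean polysemy 7 -> ~0.14, the low end seen on broad corpora
        assert ss.clarity(make_stats(7, 7, 7)) == pytest.approx(1 / 7)

    def test_clarity_vacuous_without_interpretable_terms(self):
        assert ss.clarity(make_stats(0, 0)) == 1.0

    def test_clarity_empty_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            ss.clarity([])

    @given(st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=20),
           st.data())
    def test_raising_sense_count_never_raises_clarity(self, senses, data):
        idx = data.draw(st.integers(min_value=0, max_value=len(senses) - 1))
        bumped = list(senses)
        bumped[idx] += 1
        assert ss.clarity(make_stats(*bumped)) <= ss.clarity(make_stats(*senses)) + 1e-12


class TestPragmaticSocial:
    @pytest.mark.parametrize(
        "counts,total,expected",
        [
            (ElementCounts(50, 1, 1), 100, 0.52),
            (ElementCounts(0, 0, 0), 100, 0.0),
            (ElementCounts(3, 2, 1), 6, 1.0),
        ],
    )
    def test_comprehensiveness(self, counts, total, expected):
        assert ss.comprehensiveness(counts, total) == pytest.approx(expected)

    def test_comprehensiveness_zero_total(self):
        with pytest.raises(ConfigurationError):
            ss.comprehensiveness(ElementCounts(1, 0, 0), 0)

    @pytest.mark.parametrize(
        "accesses,total,expected", [(0, 100, 0.0), (100, 100, 1.0), (96, 100, 0.96)]
    )
    def test_history(self, accesses, total, expected):
        assert ss.history(accesses, total) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "external,total,expected", [(0, 12, 0.0), (12, 12, 1.0), (3, 12, 0.25)]
    )
    def test_authority(self, external, total, expected):
        assert ss.authority(external, total) == pytest.approx(expected)

    def test_authority_zero_denominator_absent(self):
        assert ss.authority(0, 0) is None

    def test_manual_passthrough(self):
        assert ss.manual_subscore("accuracy", 0.9) == 0.9
        assert ss.manual_subscore("relevancy", 0.0) == 0.0

    def test_manual_out_of_range(self):
        with pytest.raises(ScoreValidationError):
            ss.manual_subscore("accuracy", 1.2)
        with pytest.raises(ScoreValidationError):
            ss.manual_subscore("novelty", 0.5)


class TestSubScoresContainer:
    def test_rejects_scores_above_one(self):
        with pytest.raises(ScoreValidationError):
            ss.SubScores(lawfulness=1.2)

    def test_only_consistency_may_be_negative(self):
        ss.SubScores(consistency=-0.17)  # observed on heavily duplicated corpora
        with pytest.raises(ScoreValidationError):
            ss.SubScores(clarity=-0.1)

    def test_present_filters_absent(self):
        sub = ss.SubScores(lawfulness=1.0, richness=0.5)
        assert sub.present() == {"lawfulness": 1.0, "richness": 0.5}
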