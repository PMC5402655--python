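"""Synthetic fixtures: closed-form expectations vs the scoring pipeline."""

import random

import pandas as pd
import pytest

from ontosemscore import inventory as inv
from ontosemscore.corpus_report import CorpusContext, score_corpus, score_document
from ontosemscore.errors import FixtureSpecError
from ontosemscore.modulation import derive_modulated_weights, mean_branch_scores
from ontosemscore.ontology_model import load_ontology_text
from ontosemscore.synthetic_fixtures import (
    FixtureSpec,
    drug_like_corpus_specs,
    generate_corpus,
    generate_ontology,
    random_fixture_spec,
)

BASIC = frozenset(
    {
        inv.SUBCLASS_OF,
        inv.LABEL_ANNOTATION,
        inv.EQUIVALENT_CLASSES,
        inv.DISJOINT_CLASSES,
        inv.COMMENT_ANNOTATION,
    }
)


class TestClosedForm:
    def test_clean_fixture_expectations(self):
        spec = FixtureSpec(
            ontology_id="clean",
            lexical_class_labels=tuple((l, 1) for l in (
                "aspirin", "ibuprofen", "insulin", "warfarin", "heparin",
                "codeine", "caffeine", "digoxin", "metformin", "morphine")),
            constructs=BASIC,
            seed=1,
        )
        expected = spec.expected_scores()
        assert expected.lawfulness == 1.0
        assert expected.richness == 0.25  # 5 of 20 constructs
        assert expected.interpretability == 1.0
        assert expected.consistency == 1.0
        assert expected.clarity == 1.0  # all labels monosemous

    def test_tripled_label_consistency(self):
        spec = FixtureSpec(
            ontology_id="dup",
            lexical_class_labels=tuple((l, 1) for l in (
                "aspirin", "ibuprofen", "insulin", "warfarin", "heparin",
                "codeine", "caffeine", "digoxin", "metformin", "naproxen")),
            duplicate_label_multiplicity={"aspirin": 3},
            constructs=BASIC,
            seed=1,
        )
        # twelve occurrences over ten distinct labels
        assert spec.expected_scores().consistency == pytest.approx(0.8)

    def test_violations_never_exceed_axioms(self):
        # each injected violation is itself an axiom, so the invariant
        # violation_count <= axiom_count holds by construction
        spec = FixtureSpec(
            ontology_id="many",
            lexical_class_labels=(("aspirin", 1), ("pain", 4)),
            constructs=frozenset({inv.SUBCLASS_OF, inv.LABEL_ANNOTATION}),
            violation_count=50,
        )
        spec.validate()
        assert spec.violation_count <= spec.expected_axiom_count()

    def test_violations_without_subclass_rejected(self):
        spec = FixtureSpec(
            ontology_id="bad",
            lexical_class_labels=(("aspirin", 1), ("pain", 4)),
            constructs=frozenset({inv.EQUIVALENT_CLASSES, inv.LABEL_ANNOTATION}),
            violation_count=1,
        )
        with pytest.raises(FixtureSpecError):
            spec.validate()

    def test_restrictions_require_subclass(self):
        spec = FixtureSpec(
            ontology_id="bad2",
            lexical_class_labels=(("aspirin", 1), ("pain", 4)),
            property_labels=(("dose", 4),),
            constructs=frozenset(
                {inv.LABEL_ANNOTATION, inv.OBJECT_PROPERTY_DECLARATION,
                 inv.EXISTENTIAL_RESTRICTION}
            ),
        )
        with pytest.raises(FixtureSpecError):
            spec.validate()


class TestGeneration:
    def test_seed_determinism_bytes(self):
        spec = FixtureSpec(
            ontology_id="det",
            lexical_class_labels=(("aspirin", 1), ("pain", 4)),
            gibberish_classes=3,
            constructs=frozenset({inv.SUBCLASS_OF, inv.LABEL_ANNOTATION}),
            seed=99,
        )
        for fmt in ("turtle", "xml"):
            a, _ = generate_ontology(spec, fmt)
            b, _ = generate_ontology(spec, fmt)
            assert a == b

    def test_different_seeds_differ_only_in_gibberish(self):
        base = dict(
            ontology_id="s", lexical_class_labels=(("aspirin", 1),),
            gibberish_classes=2,
            constructs=frozenset({inv.SUBCLASS_OF, inv.LABEL_ANNOTATION}),
        )
        a, ea = generate_ontology(FixtureSpec(seed=1, **base))
        b, eb = generate_ontology(FixtureSpec(seed=2, **base))
        assert a != b
        assert ea == eb  # expectations depend on the spec, not the seed

    @pytest.mark.parametrize("n_seeds", [40])
    def test_end_to_end_exactness(self, mini_lexicon, n_seeds):
        """Scoring a generated fixture reproduces its closed-form scores exactly."""
        rng = random.Random(7)
        for i in range(n_seeds):
            spec = random_fixture_spec(rng, mini_lexicon, f"fix{i}")
            text, expected = generate_ontology(spec)
            doc = load_ontology_text(text, "turtle")
            scored = score_document(doc, lexicon=mini_lexicon)
            for name, value in expected.present().items():
                assert getattr(scored, name) == value, (name, spec)

    def test_serialization_invariance_of_fixtures(self, mini_lexicon):
        rng = random.Random(11)
        spec = random_fixture_spec(rng, mini_lexicon, "inv")
        ttl, _ = generate_ontology(spec, "turtle")
        xml, _ = generate_ontology(spec, "xml")
        d1 = load_ontology_text(ttl, "turtle")
        d2 = load_ontology_text(xml, "xml")
        assert [a.axiom_id for a in d1.axioms] == [a.axiom_id for a in d2.axioms]
        assert d1.entities == d2.entities


class TestCorpus:
    def test_metadata_totals_match_documents(self, tmp_path, mini_lexicon):
        specs, accesses = drug_like_corpus_specs(mini_lexicon, seed=4)
        manifest = generate_corpus(specs, accesses, tmp_path)
        frame = pd.read_csv(manifest.metadata_path)
        for spec in specs:
            row = frame[frame["id"] == spec.ontology_id].iloc[0]
            doc = load_ontology_text(
                manifest.paths[spec.ontology_id].read_text(), "turtle"
            )
            assert row["classes"] == len(doc.entities["class"])
            assert row["properties"] == len(doc.entities["object_property"])
            assert row["instances"] == len(doc.entities["individual"])

    def test_duplicate_ids_rejected(self, tmp_path, mini_lexicon):
        specs, accesses = drug_like_corpus_specs(mini_lexicon, seed=4)
        with pytest.raises(FixtureSpecError):
            generate_corpus([specs[0], specs[0]], accesses[:2], tmp_path)

    def test_access_shares(self, tmp_path, mini_lexicon):
        specs, _ = drug_like_corpus_specs(mini_lexicon, seed=4)
        manifest = generate_corpus(specs[:2], [96, 4], tmp_path)
        context = CorpusContext.from_csv(manifest.metadata_path)
        reports = score_corpus(dict(manifest.paths), context, mini_lexicon)
        histories = sorted(r.subscores.history for r in reports)
        assert histories == pytest.approx([0.04, 0.96])

    def test_identical_members_share_equally(self, tmp_path, mini_lexicon):
        base = drug_like_corpus_specs(mini_lexicon, seed=4)[0][0]
        specs = [
            FixtureSpec(
                ontology_id=f"twin{i}",
                lexical_class_labels=base.lexical_class_labels,
                gibberish_classes=base.gibberish_classes,
                property_labels=base.property_labels,
                constructs=base.constructs,
                seed=base.seed,
            )
            for i in range(4)
        ]
        manifest = generate_corpus(specs, [10] * 4, tmp_path)
        context = CorpusContext.from_csv(manifest.metadata_path)
        reports = score_corpus(dict(manifest.paths), context, mini_lexicon)
        for report in reports:
            assert report.subscores.comprehensiveness == pytest.approx(0.25)

    def test_engineered_corpus_reproduces_modulated_weights(self, tmp_path, mini_lexicon):
        """A corpus engineered to the drug-profile branch means modulates to
        the published weight tuple."""
        specs, accesses = drug_like_corpus_specs(mini_lexicon, seed=8)
        manifest = generate_corpus(specs, accesses, tmp_path)
        context = CorpusContext.from_csv(manifest.metadata_path)
        reports = score_corpus(dict(manifest.paths), context, mini_lexicon)
        means = mean_branch_scores({r.ontology_id: r.branches for r in reports})
        assert means == {
            "syntactic": 0.67, "semantic": 0.83, "pragmatic": 0.14, "social": 0.14
        }
        assert derive_modulated_weights(means) == {
            "syntactic": 0.38, "semantic": 0.46, "pragmatic": 0.08, "social": 0.08
        }
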