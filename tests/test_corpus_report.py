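"""Corpus scoring, aggregate statistics and rendering."""

import random

import numpy as np
import pandas as pd
import pytest

from ontosemscore.aggregation import (
    BranchScores,
    EQUAL_WEIGHTS,
    QualityReport,
    branch_scores,
    overall_quality,
)
from ontosemscore.corpus_report import (
    CorpusContext,
    CorpusEntry,
    aggregate_stats,
    render_report,
    score_corpus,
    score_document,
)
from ontosemscore.datasets import drug_ontology_scores
from ontosemscore.errors import DegenerateCorpusError
from ontosemscore.ontology_model import ElementCounts
from ontosemscore.subscores import SubScores
from ontosemscore.synthetic_fixtures import (
    drug_like_corpus_specs,
    generate_corpus,
    random_fixture_spec,
)


@pytest.fixture(scope="module")
def scored_corpus(tmp_path_factory, mini_lexicon):
    rng = random.Random(2024)
    specs = [random_fixture_spec(rng, mini_lexicon, f"member{i}") for i in range(5)]
    accesses = [rng.randint(1, 500) for _ in specs]
    manifest = generate_corpus(specs, accesses, tmp_path_factory.mktemp("corpus"))
    context = CorpusContext.from_csv(manifest.metadata_path)
    reports = score_corpus(dict(manifest.paths), context, mini_lexicon)
    return manifest, context, reports


class TestCorpusContext:
    def test_totals_equal_entry_sums(self, scored_corpus):
        _, context, _ = scored_corpus
        assert context.total_elements == sum(e.counts.total() for e in context.entries)
        assert context.total_accesses == sum(e.accesses for e in context.entries)

    def test_duplicate_ids_rejected(self):
        entry = CorpusEntry("x", ElementCounts(1, 0, 0), 1)
        with pytest.raises(DegenerateCorpusError):
            CorpusContext(entries=(entry, entry))


class TestScoreCorpus:
    def test_comprehensiveness_partition(self, scored_corpus):
        _, _, reports = scored_corpus
        assert sum(r.subscores.comprehensiveness for r in reports) == pytest.approx(1.0)
        assert sum(r.subscores.history for r in reports) == pytest.approx(1.0)

    def test_corpus_of_one(self, tmp_path, mini_lexicon):
        specs, _ = drug_like_corpus_specs(mini_lexicon, seed=5)
        manifest = generate_corpus(specs[:1], [10], tmp_path)
        context = CorpusContext.from_csv(manifest.metadata_path)
        (report,) = score_corpus(dict(manifest.paths), context, mini_lexicon)
        assert report.subscores.comprehensiveness == 1.0
        assert report.subscores.history == 1.0

    def test_unloadable_member_excluded(self, tmp_path, mini_lexicon):
        specs, accesses = drug_like_corpus_specs(mini_lexicon, seed=3)
        manifest = generate_corpus(specs[:3], accesses[:3], tmp_path)
        broken = tmp_path / "broken.ttl"
        broken.write_text("this is not turtle @@@", encoding="utf-8")
        sources = dict(manifest.paths)
        sources["broken"] = broken
        context = CorpusContext(
            entries=CorpusContext.from_csv(manifest.metadata_path).entries
            + (CorpusEntry("broken", ElementCounts(1, 0, 0), 1),)
        )
        reports = score_corpus(sources, context, mini_lexicon)
        assert {r.ontology_id for r in reports} == set(manifest.paths)

    def test_removing_member_raises_others_shares(self, scored_corpus, mini_lexicon):
        manifest, context, reports = scored_corpus
        kept = dict(list(manifest.paths.items())[:-1])
        smaller = CorpusContext(
            entries=tuple(e for e in context.entries if e.ontology_id in kept)
        )
        smaller_reports = score_corpus(kept, smaller, mini_lexicon)
        before = {
            r.ontology_id: (r.subscores.comprehensiveness, r.subscores.history)
            for r in reports
        }
        for report in smaller_reports:
            assert report.subscores.comprehensiveness >= before[report.ontology_id][0]
            assert report.subscores.history >= before[report.ontology_id][1]

    def test_manual_scores_flow_through(self, tmp_path, mini_lexicon):
        specs, accesses = drug_like_corpus_specs(mini_lexicon, seed=9)
        manifest = generate_corpus(specs[:2], accesses[:2], tmp_path)
        context = CorpusContext.from_csv(manifest.metadata_path)
        reports = score_corpus(
            dict(manifest.paths), context, mini_lexicon,
            manual={specs[0].ontology_id: {"accuracy": 0.9, "relevancy": 0.5}},
        )
        by_id = {r.ontology_id: r for r in reports}
        assert by_id[specs[0].ontology_id].subscores.accuracy == 0.9
        assert by_id[specs[1].ontology_id].subscores.accuracy is None


def reports_from_reference_table():
    """Build QualityReports from the bundled drug-ontology benchmark table."""
    frame = drug_ontology_scores()
    reports = []
    for ontology_id, row in frame.iterrows():
        sub = SubScores(
            lawfulness=row["lawfulness"], richness=row["richness"],
            interpretability=row["interpretability"], consistency=row["consistency"],
            clarity=row["clarity"], comprehensiveness=row["comprehensiveness"],
            history=row["history"],
        )
        branches = BranchScores(
            syntactic=row["syntactic"], semantic=row["semantic"],
            pragmatic=row["pragmatic"], social=row["social"],
        )
        reports.append(
            overall_quality(branches, EQUAL_WEIGHTS, str(ontology_id), subscores=sub)
        )
    return reports


class TestAggregateStats:
    def test_reference_lawfulness_row(self):
        stats = aggregate_stats(reports_from_reference_table())
        row = stats.row("lawfulness")
        assert round(row["mean"], 2) == 0.97
        assert row["median"] == 1.00
        assert row["min"] == 0.91
        assert row["max"] == 1.00

    def test_single_report_degenerate_stats(self):
        report = reports_from_reference_table()[0]
        stats = aggregate_stats([report])
        row = stats.row("lawfulness")
        assert row["mean"] == row["min"] == row["max"] == row["median"]
        assert row["sd"] == 0.0

    def test_matches_independent_recomputation(self, scored_corpus):
        _, _, reports = scored_corpus
        stats = aggregate_stats(reports)
        values = [r.subscores.lawfulness for r in reports]
        n = len(values)
        mean = sum(values) / n
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        assert stats.row("lawfulness")["mean"] == pytest.approx(mean)
        assert stats.row("lawfulness")["sd"] == pytest.approx(var ** 0.5)
        assert stats.row("lawfulness")["median"] == pytest.approx(
            float(np.median(values))
        )

    def test_permutation_invariance(self, scored_corpus):
        _, _, reports = scored_corpus
        a = aggregate_stats(reports).frame
        b = aggregate_stats(list(reversed(reports))).frame
        pd.testing.assert_frame_equal(a, b)

    def test_empty_is_an_error(self):
        with pytest.raises(DegenerateCorpusError):
            aggregate_stats([])


class TestRendering:
    def test_bit_stable(self, scored_corpus):
        _, _, reports = scored_corpus
        stats = aggregate_stats(reports)
        for fmt in ("json", "csv", "markdown"):
            assert render_report(reports, stats=stats, fmt=fmt) == render_report(
                reports, stats=stats, fmt=fmt
            )

    def test_markdown_row_count(self, scored_corpus):
        _, _, reports = scored_corpus
        stats = aggregate_stats(reports)
        lines = render_report(reports, stats=stats, fmt="markdown").strip().splitlines()
        # header + separator + one row per ontology + five summary rows
        assert len(lines) == 2 + len(reports) + 5

    def test_csv_round_trip_full_precision(self, scored_corpus):
        _, _, reports = scored_corpus
        text = render_report(reports, fmt="csv")
        frame = pd.read_csv(__import__("io").StringIO(text))
        for report, (_, row) in zip(reports, frame.iterrows()):
            assert row["overall"] == report.quality
            assert row["lawfulness"] == report.subscores.lawfulness

    def test_unknown_format(self, scored_corpus):
        _, _, reports = scored_corpus
        with pytest.raises(Exception, match="format"):
            render_report(reports, fmt="xlsx")
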