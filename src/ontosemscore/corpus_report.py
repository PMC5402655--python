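"""Corpus scoring, aggregate statistics and report rendering.

Comprehensiveness and history are *corpus-relative*: an ontology's share of
all classes+instances+properties, and of all access counts, in the corpus
it is compared against.  The per-ontology element and access counts come
from a local metadata table (the snapshot a repository's REST API would
return), not from the parsed files, so scoring is hermetic.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import subscores as ss
from .aggregation import (
    BRANCHES,
    BranchScores,
    QualityReport,
    branch_scores,
    overall_quality,
    round_report,
)
from .config import DEFAULT_CONFIG, ScoringConfig
from .errors import DegenerateCorpusError, OntoSemScoreError, UndefinedScoreError
from .lexicon import WordSenseLexicon, term_sense_stats
from .ontology_model import (
    ElementCounts,
    OntologyDocument,
    count_elements,
    detect_violations,
    extract_terms,
    feature_usage,
    load_ontology,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Corpus metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusEntry:
    ontology_id: str
    counts: ElementCounts
    accesses: int


@dataclass(frozen=True)
class CorpusContext:
    """Per-ontology element/access counts plus corpus totals."""

    entries: tuple[CorpusEntry, ...]
    snapshot: str = ""

    def __post_init__(self) -> None:
        ids = [e.ontology_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise DegenerateCorpusError("duplicate ontology ids in corpus metadata")

    @property
    def total_elements(self) -> int:
        return sum(e.counts.total() for e in self.entries)

    @property
    def total_accesses(self) -> int:
        return sum(e.accesses for e in self.entries)

    def entry(self, ontology_id: str) -> Optional[CorpusEntry]:
        for e in self.entries:
            if e.ontology_id == ontology_id:
                return e
        return None

    @classmethod
    def from_csv(cls, path: str | Path, snapshot: str = "") -> "CorpusContext":
        """Read a metadata table with columns id, classes, instances,
        properties, accesses."""
        frame = pd.read_csv(path)
        entries = tuple(
            CorpusEntry(
                ontology_id=str(row["id"]),
                counts=ElementCounts(
                    classes=int(row["classes"]),
                    instances=int(row["instances"]),
                    properties=int(row["properties"]),
                ),
                accesses=int(row["accesses"]),
            )
            for _, row in frame.iterrows()
        )
        return cls(entries=entries, snapshot=snapshot or str(path))

    @classmethod
    def from_documents(
        cls,
        documents: Mapping[str, OntologyDocument],
        accesses: Mapping[str, int],
        snapshot: str = "derived-from-documents",
    ) -> "CorpusContext":
        entries = tuple(
            CorpusEntry(
                ontology_id=ontology_id,
                counts=count_elements(doc),
                accesses=int(accesses.get(ontology_id, 0)),
            )
            for ontology_id, doc in documents.items()
        )
        return cls(entries=entries, snapshot=snapshot)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def score_document(
    doc: OntologyDocument,
    lexicon: WordSenseLexicon,
    config: ScoringConfig = DEFAULT_CONFIG,
    context: CorpusContext | None = None,
    ontology_id: str | None = None,
    accuracy: float | None = None,
    relevancy: float | None = None,
) -> ss.SubScores:
    """Compute every sub-score obtainable from the inputs at hand.

    Sub-scores whose inputs are unavailable (corpus-relative scores without
    a context, semantic scores of a termless ontology) come back absent.
    """
    report = detect_violations(doc)
    used, size = feature_usage(doc, config.inventory)
    terms = extract_terms(doc)
    stats = [term_sense_stats(t, lexicon) for t in terms]

    def guarded(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except UndefinedScoreError:
            return None

    values: dict[str, Optional[float]] = {
        "lawfulness": ss.lawfulness(report),
        "richness": ss.richness(len(used), size),
        "interpretability": guarded(ss.interpretability, stats),
        "consistency": guarded(
            ss.consistency, terms, formula=config.consistency_formula
        ),
        "clarity": guarded(ss.clarity, stats),
        "authority": ss.authority(
            len(doc.external_namespace_refs), len(doc.referenced_namespaces)
        ),
        "accuracy": None if accuracy is None else ss.manual_subscore("accuracy", accuracy),
        "relevancy": None if relevancy is None else ss.manual_subscore("relevancy", relevancy),
        "comprehensiveness": None,
        "history": None,
    }
    if context is not None and ontology_id is not None:
        entry = context.entry(ontology_id)
        if entry is not None:
            if context.total_elements > 0:
                values["comprehensiveness"] = ss.comprehensiveness(
                    entry.counts, context.total_elements
                )
            if context.total_accesses > 0:
                values["history"] = ss.history(entry.accesses, context.total_accesses)
    return ss.SubScores(**values)


def score_corpus(
    sources: Mapping[str, OntologyDocument | str | Path],
    context: CorpusContext,
    lexicon: WordSenseLexicon,
    config: ScoringConfig = DEFAULT_CONFIG,
    manual: Mapping[str, Mapping[str, float]] | None = None,
) -> list[QualityReport]:
    """Score every member of a corpus.

    ``sources`` maps ontology ids to loaded documents or file paths.
    Unloadable members are skipped with a logged exclusion, mirroring how
    survey corpora drop files with broken serializations.
    """
    manual = manual or {}
    reports: list[QualityReport] = []
    for ontology_id, source in sources.items():
        if isinstance(source, OntologyDocument):
            doc = source
        else:
            try:
                doc = load_ontology(source, inventory=config.inventory)
            except OntoSemScoreError as exc:
                logger.warning("excluding %s from corpus: %s", ontology_id, exc)
                continue
        extra = manual.get(ontology_id, {})
        sub = score_document(
            doc,
            lexicon=lexicon,
            config=config,
            context=context,
            ontology_id=ontology_id,
            accuracy=extra.get("accuracy"),
            relevancy=extra.get("relevancy"),
        )
        branches = branch_scores(sub, config.weights)
        reports.append(
            overall_quality(
                branches, config.weights, ontology_id=ontology_id, subscores=sub
            )
        )
    if not reports:
        raise DegenerateCorpusError("no corpus member could be scored")
    return reports


# ---------------------------------------------------------------------------
# Aggregate statistics
# ---------------------------------------------------------------------------

_STAT_COLUMNS = ("mean", "sd", "min", "max", "median")


@dataclass(frozen=True)
class StatsTable:
    """Per-score rows of (mean, sd, min, max, median).

    Standard deviation is the sample convention (n−1).  Absent scores are
    excluded from their row rather than treated as zero.
    """

    frame: pd.DataFrame = field(repr=False)

    def row(self, score: str) -> dict[str, float]:
        return {c: float(self.frame.loc[score, c]) for c in _STAT_COLUMNS}


def aggregate_stats(reports: Sequence[QualityReport]) -> StatsTable:
    """Basic statistics of every sub-score, branch score and overall score."""
    if not reports:
        raise DegenerateCorpusError("no reports to aggregate")
    columns: dict[str, list[float]] = {}
    for report in reports:
        for name, value in report.subscores.as_dict().items():
            columns.setdefault(name, []).append(np.nan if value is None else value)
        for name, value in report.branches.as_dict().items():
            columns.setdefault(name, []).append(np.nan if value is None else value)
        columns.setdefault("overall", []).append(report.quality)
    rows = {}
    for name, values in columns.items():
        series = pd.Series(values, dtype=float).dropna()
        if series.empty:
            continue
        rows[name] = {
            "mean": series.mean(),
            "sd": series.std(ddof=1) if len(series) > 1 else 0.0,
            "min": series.min(),
            "max": series.max(),
            "median": series.median(),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(_STAT_COLUMNS)]
    return StatsTable(frame=frame)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _report_record(report: QualityReport) -> dict:
    record: dict = {"id": report.ontology_id}
    record.update(report.subscores.as_dict())
    record.update(report.branches.as_dict())
    record["overall"] = report.quality
    return record


def render_report(
    reports: Sequence[QualityReport],
    stats: StatsTable | None = None,
    comparison=None,
    fmt: str = "json",
) -> str:
    """Serialize reports (plus optional statistics and comparison).

    Output is bit-stable for fixed inputs: keys sorted, two-decimal
    formatting in the human-readable markdown, full precision in JSON/CSV.
    """
    if fmt == "json":
        payload: dict = {"ontologies": [_report_record(r) for r in reports]}
        if stats is not None:
            payload["statistics"] = {
                score: stats.row(score) for score in sorted(stats.frame.index)
            }
        if comparison is not None:
            payload["comparison"] = {
                "rows": [
                    {
                        "id": row.ontology_id,
                        comparison.label_a: row.q_a,
                        comparison.label_b: row.q_b,
                        "diff": row.diff,
                    }
                    for row in comparison.rows
                ],
                "summary": comparison.summary(),
            }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"
    if fmt == "csv":
        buffer = io.StringIO()
        records = [_report_record(r) for r in reports]
        fieldnames = list(records[0].keys())
        writer = csv.DictWriter(buffer, fieldnames=fieldnames, lineterminator="\n")
        writer.writeheader()
        for record in records:
            writer.writerow({k: "" if v is None else repr(v) if isinstance(v, float) else v
                             for k, v in record.items()})
        return buffer.getvalue()
    if fmt == "markdown":
        records = [_report_record(r) for r in reports]
        headers = list(records[0].keys())
        def cell(v):
            if v is None:
                return "—"
            if isinstance(v, float):
                return f"{round_report(v):.2f}"
            return str(v)
        lines = ["| " + " | ".join(headers) + " |",
                 "|" + "|".join("---" for _ in headers) + "|"]
        for record in records:
            lines.append("| " + " | ".join(cell(record[h]) for h in headers) + " |")
        if stats is not None:
            for stat in ("mean", "sd", "min", "max", "median"):
                cells = [f"**{stat}**"]
                for h in headers[1:]:
                    if h in stats.frame.index:
                        cells.append(f"{round_report(float(stats.frame.loc[h, stat])):.2f}")
                    else:
                        cells.append("—")
                lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise OntoSemScoreError(f"unknown report format {fmt!r}")
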