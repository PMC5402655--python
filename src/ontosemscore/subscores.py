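"""The ten quality sub-scores.

Syntactic: lawfulness (S_L) and richness (S_R).
Semantic: interpretability (E_I), consistency (E_C), clarity (E_A).
Pragmatic: comprehensiveness (P_O), accuracy (P_U), relevancy (P_R).
Social: authority (O_T) and history (O_H).

All sub-scores are ratios oriented so that 1 is best.  Every present score
is at most 1; all are nonnegative except consistency, which goes negative
under heavy duplication (a corpus where every label is tripled scores −1).
Accuracy and relevancy require expert review and are injected manually.

Formula choices that the framework's prose leaves open are documented here
and selectable where noted:

* lawfulness is ``1 − violations/axioms`` (violation fraction, inverted so
  that 1 means standards-clean);
* consistency defaults to ``1 − (T − U)/U`` with T term occurrences and U
  distinct normalized terms — the only variant that can produce the
  negative scores observed on heavily duplicated real ontologies; the
  milder duplicate fraction ``1 − (T − U)/T`` is selectable;
* clarity is the reciprocal of mean polysemy over interpretable terms,
  clamped to [0, 1], and vacuously 1 when no term is interpretable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable, Optional

from .errors import (
    ConfigurationError,
    InternalConsistencyError,
    ScoreValidationError,
    UndefinedScoreError,
)
from .lexicon import TermSenseStats
from .ontology_model import ElementCounts, Term, ViolationReport

#: field name → conventional symbol
SYMBOLS = {
    "lawfulness": "S_L",
    "richness": "S_R",
    "interpretability": "E_I",
    "consistency": "E_C",
    "clarity": "E_A",
    "comprehensiveness": "P_O",
    "accuracy": "P_U",
    "relevancy": "P_R",
    "authority": "O_T",
    "history": "O_H",
}

#: sub-score field names by branch
BRANCH_MEMBERS = {
    "syntactic": ("lawfulness", "richness"),
    "semantic": ("interpretability", "consistency", "clarity"),
    "pragmatic": ("comprehensiveness", "accuracy", "relevancy"),
    "social": ("authority", "history"),
}


@dataclass(frozen=True)
class SubScores:
    """The ten sub-scores; ``None`` means "not computed" (absent)."""

    lawfulness: Optional[float] = None
    richness: Optional[float] = None
    interpretability: Optional[float] = None
    consistency: Optional[float] = None
    clarity: Optional[float] = None
    comprehensiveness: Optional[float] = None
    accuracy: Optional[float] = None
    relevancy: Optional[float] = None
    authority: Optional[float] = None
    history: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if value > 1 + 1e-12:
                raise ScoreValidationError(f"{f.name} score {value} exceeds 1")
            if f.name != "consistency" and value < -1e-12:
                raise ScoreValidationError(f"{f.name} score {value} is negative")

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def present(self) -> dict[str, float]:
        return {k: v for k, v in self.as_dict().items() if v is not None}


# ---------------------------------------------------------------------------
# Syntactic
# ---------------------------------------------------------------------------


def lawfulness(report: ViolationReport) -> float:
    """Fraction of axioms free of standards violations: ``1 − V/A``.

    An ontology with no axioms at all is vacuously lawful (score 1).
    """
    if report.total_axioms == 0:
        return 1.0
    if report.violating_axioms > report.total_axioms:
        raise InternalConsistencyError("more violating axioms than axioms")
    return 1.0 - report.violating_axioms / report.total_axioms


def richness(used_count: int, inventory_size: int) -> float:
    """Fraction of the construct inventory actually used."""
    if inventory_size <= 0:
        raise ConfigurationError("inventory size must be positive")
    if not 0 <= used_count <= inventory_size:
        raise InternalConsistencyError(
            f"used construct count {used_count} outside [0, {inventory_size}]"
        )
    return used_count / inventory_size


# ---------------------------------------------------------------------------
# Semantic
# ---------------------------------------------------------------------------


def interpretability(stats: Iterable[TermSenseStats]) -> float:
    """Fraction of terms with at least one word sense."""
    stats = list(stats)
    if not stats:
        raise UndefinedScoreError("interpretability is undefined without terms")
    return sum(1 for s in stats if s.interpretable) / len(stats)


def consistency(terms: Iterable[Term], formula: str = "distinct-ratio") -> float:
    """Penalize duplicated normalized terms.

    With T occurrences and U distinct normalized terms, the default
    ``distinct-ratio`` formula is ``1 − (T − U)/U`` (1 when all distinct,
    negative when duplicates outnumber distinct terms).  The alternative
    ``duplicate-fraction`` is ``1 − (T − U)/T``, bounded below by 0.
    """
    keys = [t.key for t in terms]
    if not keys:
        raise UndefinedScoreError("consistency is undefined without terms")
    occurrences = len(keys)
    distinct = len(Counter(keys))
    duplicates = occurrences - distinct
    if formula == "distinct-ratio":
        return 1.0 - duplicates / distinct
    if formula == "duplicate-fraction":
        return 1.0 - duplicates / occurrences
    raise ConfigurationError(f"unknown consistency formula {formula!r}")


def clarity(stats: Iterable[TermSenseStats]) -> float:
    """Inverse ambiguity: reciprocal of mean polysemy over interpretable terms.

    ``min(1, N / Σ senses)`` where N counts interpretable terms and the sum
    runs over their sense counts.  All-monosemous → 1.  With no
    interpretable term the vocabulary is vacuously unambiguous (score 1).
    """
    stats = list(stats)
    if not stats:
        raise UndefinedScoreError("clarity is undefined without terms")
    interpretable = [s for s in stats if s.interpretable]
    if not interpretable:
        return 1.0
    total_senses = sum(s.sense_count for s in interpretable)
    return min(1.0, len(interpretable) / total_senses)


# ---------------------------------------------------------------------------
# Pragmatic
# ---------------------------------------------------------------------------


def comprehensiveness(counts: ElementCounts, corpus_total: int) -> float:
    """The ontology's share of classes+instances+properties in its corpus."""
    if corpus_total <= 0:
        raise ConfigurationError("corpus element total must be positive")
    if counts.total() > corpus_total:
        raise InternalConsistencyError(
            "ontology has more elements than the corpus total"
        )
    return counts.total() / corpus_total


def manual_subscore(kind: str, value: float) -> float:
    """Store an externally supplied accuracy (P_U) or relevancy (P_R) score."""
    if kind not in ("accuracy", "relevancy"):
        raise ScoreValidationError(f"unknown manual sub-score kind {kind!r}")
    if not 0.0 <= value <= 1.0:
        raise ScoreValidationError(f"{kind} value {value} outside [0, 1]")
    return float(value)


# ---------------------------------------------------------------------------
# Social
# ---------------------------------------------------------------------------


def authority(external_refs: int, reference_total: int) -> Optional[float]:
    """Share of referenced namespaces that link out to other ontologies.

    Returns ``None`` (score absent) when the ontology references no
    namespaces at all.
    """
    if reference_total == 0:
        return None
    if not 0 <= external_refs <= reference_total:
        raise InternalConsistencyError(
            f"external reference count {external_refs} outside [0, {reference_total}]"
        )
    return external_refs / reference_total


def history(accesses: int, corpus_total_accesses: int) -> float:
    """The ontology's share of access counts in its corpus."""
    if corpus_total_accesses <= 0:
        raise ConfigurationError("corpus access total must be positive")
    if not 0 <= accesses <= corpus_total_accesses:
        raise InternalConsistencyError(
            "ontology access count outside [0, corpus total]"
        )
    return accesses / corpus_total_accesses
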