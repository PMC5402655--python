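"""Corpus-tailored weight modulation and equal-vs-modulated comparison.

A corpus of similar ontologies (e.g. the drug ontologies on a repository)
tends to be systematically strong in some branches and weak in others.
Modulation converts the corpus's mean branch scores proportionally into
branch weights, so that the aspects in which the corpus is strong carry
more weight: weight_i = mean_i / Σ means, rounded to two decimals by
largest-remainder apportionment so the rounded weights still sum to
exactly 1.00.  (Naive per-entry rounding can sum to 0.99 or 1.01 —
largest-remainder is what preserves both the proportions and the total.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .aggregation import (
    BRANCHES,
    BranchScores,
    WeightConfig,
    overall_quality,
    round_report,
)
from .errors import ConfigurationError, DegenerateCorpusError

_EPS = 1e-9


def largest_remainder_round(shares: Mapping[str, float], digits: int = 2) -> dict[str, float]:
    """Round nonnegative proportions summing to 1 so the total is preserved.

    Each share is floored at the target precision; the leftover units are
    assigned to the largest fractional remainders (ties broken by input
    order).  Deterministic and permutation-equivariant up to exact ties.
    """
    scale = 10 ** digits
    keys = list(shares)
    scaled = {k: shares[k] * scale for k in keys}
    base = {k: int(math.floor(scaled[k] + _EPS)) for k in keys}
    remainder = {k: max(0.0, scaled[k] - base[k]) for k in keys}
    leftover = scale - sum(base.values())
    if leftover < 0:
        # floating-point guard pushed a floor too high; take back from the
        # smallest remainders
        for k in sorted(keys, key=lambda k: remainder[k]):
            if leftover == 0:
                break
            base[k] -= 1
            leftover += 1
    for k in sorted(keys, key=lambda k: -remainder[k]):
        if leftover == 0:
            break
        base[k] += 1
        leftover -= 1
    return {k: base[k] / scale for k in keys}


def derive_modulated_weights(
    mean_branches: Mapping[str, float], digits: int = 2
) -> dict[str, float]:
    """Convert mean branch scores proportionally into branch weights.

    ``mean_branches`` maps branch names (syntactic, semantic, pragmatic,
    social) to nonnegative corpus means; means should be supplied at the
    precision at which they are reported (conventionally two decimals).
    """
    unknown = set(mean_branches) - set(BRANCHES)
    if unknown:
        raise ConfigurationError(f"unknown branches: {sorted(unknown)}")
    if any(v < 0 for v in mean_branches.values()):
        raise DegenerateCorpusError("negative mean branch score")
    total = sum(mean_branches.values())
    if total <= 0:
        raise DegenerateCorpusError("all mean branch scores are zero")
    shares = {k: v / total for k, v in mean_branches.items()}
    return largest_remainder_round(shares, digits=digits)


@dataclass(frozen=True)
class ComparisonRow:
    ontology_id: str
    q_a: float
    q_b: float

    @property
    def diff(self) -> float:
        return self.q_b - self.q_a


@dataclass(frozen=True)
class ComparisonTable:
    """Per-ontology overall scores under two weight configurations."""

    rows: tuple[ComparisonRow, ...]
    label_a: str = "Q_EW"
    label_b: str = "Q_mod"

    def _column(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.rows], dtype=float)

    def summary(self) -> dict[str, dict[str, float]]:
        """Mean and sample standard deviation of each column."""
        out = {}
        for label, attr in ((self.label_a, "q_a"), (self.label_b, "q_b"), ("diff", "diff")):
            col = self._column(attr)
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            out[label] = {"mean": float(col.mean()), "sd": sd}
        return out


def compare_scorings(
    branch_table: Mapping[str, BranchScores] | Sequence[tuple[str, BranchScores]],
    config_a: WeightConfig,
    config_b: WeightConfig,
    labels: tuple[str, str] = ("Q_EW", "Q_mod"),
) -> ComparisonTable:
    """Score every ontology under both configurations and tabulate the shift."""
    if isinstance(branch_table, Mapping):
        items = list(branch_table.items())
    else:
        items = list(branch_table)
    if not items:
        raise DegenerateCorpusError("comparison over an empty corpus")
    rows = tuple(
        ComparisonRow(
            ontology_id=ontology_id,
            q_a=overall_quality(branches, config_a, ontology_id).quality,
            q_b=overall_quality(branches, config_b, ontology_id).quality,
        )
        for ontology_id, branches in items
    )
    return ComparisonTable(rows=rows, label_a=labels[0], label_b=labels[1])


def mean_branch_scores(
    branch_table: Mapping[str, BranchScores] | Sequence[tuple[str, BranchScores]],
    digits: Optional[int] = 2,
    statistic: str = "mean",
) -> dict[str, float]:
    """Central branch scores over a corpus, absent branches counted as 0.

    By default the per-branch mean is rounded half-up to reporting
    precision (two decimals) before use, matching how modulation is driven
    from a reported score table; pass ``digits=None`` for full precision.
    ``statistic="median"`` substitutes the median as the location measure.
    """
    if isinstance(branch_table, Mapping):
        table = list(branch_table.values())
    else:
        table = [b for _, b in branch_table]
    if not table:
        raise DegenerateCorpusError("empty corpus")
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"unknown location statistic {statistic!r}")
    means = {}
    for branch in BRANCHES:
        values = [b.as_dict()[branch] or 0.0 for b in table]
        if statistic == "mean":
            center = sum(values) / len(values)
        else:
            center = float(np.median(values))
        means[branch] = round_report(center, digits) if digits is not None else center
    return means
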