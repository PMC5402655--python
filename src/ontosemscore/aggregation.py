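"""Weighted aggregation of sub-scores into branch scores and overall quality.

The overall quality of an ontology is

    Q = w_q1·S + w_q2·E + w_q3·P + w_q4·O

where S, E, P, O are the syntactic, semantic, pragmatic and social branch
scores, themselves weighted combinations of their sub-scores.  Sub-scores
that could not be computed (no expert review for accuracy/relevancy, no
corpus context, …) are *absent*; their weight is redistributed
proportionally over the present members, so e.g. a pragmatic branch with
only comprehensiveness present simply equals comprehensiveness.

All arithmetic is kept at full precision; rounding to two decimals happens
only when a report is rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

from .errors import ConfigurationError, UndefinedScoreError
from .subscores import BRANCH_MEMBERS, SubScores

BRANCHES = ("syntactic", "semantic", "pragmatic", "social")


def round_report(value: float, digits: int = 2) -> float:
    """Half-up decimal rounding used at report time."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _default_sub_weights() -> dict[str, dict[str, float]]:
    weights: dict[str, dict[str, float]] = {}
    for branch, members in BRANCH_MEMBERS.items():
        weights[branch] = {m: 1.0 / len(members) for m in members}
    # authority needs a citation graph that repository metadata does not
    # provide; it is excluded from default scoring (weight 0), so the social
    # branch defaults to the history score alone
    weights["social"] = {"authority": 0.0, "history": 1.0}
    return weights


@dataclass(frozen=True)
class WeightConfig:
    """Branch weights and per-branch sub-score weights (all nonnegative).

    Weights need not be normalized on input; each group is renormalized over
    the sub-scores actually present when a score is computed.
    """

    branch_weights: Mapping[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in BRANCHES}
    )
    sub_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_sub_weights
    )

    def __post_init__(self) -> None:
        for name, w in self.branch_weights.items():
            if name not in BRANCHES:
                raise ConfigurationError(f"unknown branch {name!r}")
            if w < 0:
                raise ConfigurationError(f"negative weight for branch {name}")
        for branch, group in self.sub_weights.items():
            if branch not in BRANCH_MEMBERS:
                raise ConfigurationError(f"unknown branch {branch!r}")
            for member, w in group.items():
                if member not in BRANCH_MEMBERS[branch]:
                    raise ConfigurationError(
                        f"{member!r} is not a sub-score of the {branch} branch"
                    )
                if w < 0:
                    raise ConfigurationError(f"negative weight for {member}")

    def with_branch_weights(self, branch_weights: Mapping[str, float]) -> "WeightConfig":
        return replace(self, branch_weights=dict(branch_weights))


EQUAL_WEIGHTS = WeightConfig()


@dataclass(frozen=True)
class BranchScores:
    """Branch scores; ``None`` means every sub-score of the branch was absent."""

    syntactic: Optional[float] = None
    semantic: Optional[float] = None
    pragmatic: Optional[float] = None
    social: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {b: getattr(self, b) for b in BRANCHES}

    def present(self) -> dict[str, float]:
        return {k: v for k, v in self.as_dict().items() if v is not None}


@dataclass(frozen=True)
class QualityReport:
    """Overall quality of one ontology with full provenance."""

    ontology_id: str
    subscores: SubScores
    branches: BranchScores
    quality: float
    weights: WeightConfig
    notes: tuple[str, ...] = ()

    @property
    def quality_2dp(self) -> float:
        return round_report(self.quality)


def weighted_score(
    present: Mapping[str, float], weights: Mapping[str, float]
) -> Optional[float]:
    """Σ wᵢ·xᵢ with the weights renormalized over the present scores.

    Weights of absent scores are redistributed proportionally.  If every
    present score carries zero weight the score is undefined (``None``).
    """
    if not present:
        return None
    w = {k: max(0.0, weights.get(k, 0.0)) for k in present}
    total = sum(w.values())
    if total <= 0:
        return None
    return sum(w[k] / total * present[k] for k in present)


def branch_score(
    subscore_values: Mapping[str, Optional[float]],
    weights: Mapping[str, float],
) -> Optional[float]:
    """One branch score from its sub-score values (``None`` = absent)."""
    present = {k: v for k, v in subscore_values.items() if v is not None}
    return weighted_score(present, weights)


def branch_scores(sub: SubScores, config: WeightConfig = EQUAL_WEIGHTS) -> BranchScores:
    """All four branch scores of a sub-score record."""
    values = sub.as_dict()
    out = {}
    for branch, members in BRANCH_MEMBERS.items():
        out[branch] = branch_score(
            {m: values[m] for m in members}, config.sub_weights.get(branch, {})
        )
    return BranchScores(**out)


def overall_quality(
    branches: BranchScores,
    config: WeightConfig = EQUAL_WEIGHTS,
    ontology_id: str = "",
    subscores: SubScores | None = None,
    renormalize: bool = True,
) -> QualityReport:
    """Combine branch scores into the overall quality Q.

    With ``renormalize`` (the default), weights of absent branches are
    redistributed proportionally over the present ones.  With
    ``renormalize=False`` absent branches simply contribute nothing — the
    convention used when comparing corpora on a shared subset of branches.
    """
    present = branches.present()
    if not present:
        raise UndefinedScoreError("no branch score is present")
    notes = tuple(
        f"branch {b} absent; weight redistributed"
        for b in BRANCHES
        if branches.as_dict()[b] is None
    )
    if renormalize:
        q = weighted_score(present, config.branch_weights)
        if q is None:
            raise UndefinedScoreError("all present branches carry zero weight")
    else:
        q = sum(config.branch_weights.get(b, 0.0) * v for b, v in present.items())
    return QualityReport(
        ontology_id=ontology_id,
        subscores=subscores or SubScores(),
        branches=branches,
        quality=q,
        weights=config,
        notes=notes,
    )
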