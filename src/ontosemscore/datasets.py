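"""Bundled reference datasets.

``drug_ontology_scores`` is the published benchmark score table for seven
drug ontologies hosted on NCBO BioPortal (RxNORM, DIKB, DINTO, PVOnto,
VANDF, VO, DRON): per-ontology sub-scores, branch scores and overall
scores at two-decimal reporting precision.  It serves as input for
reproducing the equal-weighted vs modulated comparison without downloading
the ontologies themselves.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aggregation import BranchScores

_DRUG_SCORES_RESOURCE = "drug_ontology_scores.csv"


def drug_ontology_scores() -> pd.DataFrame:
    """The drug-ontology benchmark score table, indexed by ontology id."""
    with resources.files("ontosemscore").joinpath("data").joinpath(
        _DRUG_SCORES_RESOURCE
    ).open("r", encoding="utf-8") as handle:
        frame = pd.read_csv(handle)
    return frame.set_index("id")


def drug_ontology_branch_table() -> dict[str, BranchScores]:
    """The benchmark branch scores as a ``{id: BranchScores}`` table."""
    frame = drug_ontology_scores()
    return {
        str(ontology_id): BranchScores(
            syntactic=float(row["syntactic"]),
            semantic=float(row["semantic"]),
            pragmatic=float(row["pragmatic"]),
            social=float(row["social"]),
        )
        for ontology_id, row in frame.iterrows()
    }
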