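"""The ontology-construct inventory used by the syntactic richness score.

Richness is the fraction of a fixed inventory of OWL construct categories
that an ontology actually uses.  The inventory below is the package default:
twenty construct categories spanning the TBox (class axioms, property
axioms, restrictions), the ABox (assertions, individual identity) and the
annotation layer.  Usage is presence-based: a construct used once counts
the same as a construct used a thousand times.

The inventory is configurable; the default is deliberately fixed and
documented so that richness denominators are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

# Construct identifiers.  These double as keys in axiom records produced by
# the ontology model, so they are plain strings rather than an enum.
SUBCLASS_OF = "subclass-of"
EQUIVALENT_CLASSES = "equivalent-classes"
DISJOINT_CLASSES = "disjoint-classes"
OBJECT_PROPERTY_DECLARATION = "object-property-declaration"
DATA_PROPERTY_DECLARATION = "data-property-declaration"
ANNOTATION_PROPERTY_DECLARATION = "annotation-property-declaration"
PROPERTY_DOMAIN = "property-domain"
PROPERTY_RANGE = "property-range"
INVERSE_OF = "inverse-of"
FUNCTIONAL_PROPERTY = "functional-property"
TRANSITIVE_PROPERTY = "transitive-property"
SYMMETRIC_PROPERTY = "symmetric-property"
SUB_PROPERTY_OF = "sub-property-of"
EXISTENTIAL_RESTRICTION = "existential-restriction"
UNIVERSAL_RESTRICTION = "universal-restriction"
CARDINALITY_RESTRICTION = "cardinality-restriction"
CLASS_ASSERTION = "class-assertion"
INDIVIDUAL_IDENTITY = "individual-identity"
LABEL_ANNOTATION = "label-annotation"
COMMENT_ANNOTATION = "comment-annotation"

DEFAULT_CONSTRUCTS: tuple[str, ...] = (
    SUBCLASS_OF,
    EQUIVALENT_CLASSES,
    DISJOINT_CLASSES,
    OBJECT_PROPERTY_DECLARATION,
    DATA_PROPERTY_DECLARATION,
    ANNOTATION_PROPERTY_DECLARATION,
    PROPERTY_DOMAIN,
    PROPERTY_RANGE,
    INVERSE_OF,
    FUNCTIONAL_PROPERTY,
    TRANSITIVE_PROPERTY,
    SYMMETRIC_PROPERTY,
    SUB_PROPERTY_OF,
    EXISTENTIAL_RESTRICTION,
    UNIVERSAL_RESTRICTION,
    CARDINALITY_RESTRICTION,
    CLASS_ASSERTION,
    INDIVIDUAL_IDENTITY,
    LABEL_ANNOTATION,
    COMMENT_ANNOTATION,
)


@dataclass(frozen=True)
class FeatureInventory:
    """An ordered set of construct identifiers with a fixed size.

    The inventory is the denominator of the syntactic richness sub-score.
    """

    constructs: tuple[str, ...] = field(default=DEFAULT_CONSTRUCTS)

    def __post_init__(self) -> None:
        if not self.constructs:
            raise ConfigurationError("feature inventory must not be empty")
        if len(set(self.constructs)) != len(self.constructs):
            raise ConfigurationError("feature inventory contains duplicate identifiers")

    @property
    def size(self) -> int:
        return len(self.constructs)

    def __contains__(self, construct: str) -> bool:
        return construct in self.constructs

    def __iter__(self):
        return iter(self.constructs)


DEFAULT_INVENTORY = FeatureInventory()
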