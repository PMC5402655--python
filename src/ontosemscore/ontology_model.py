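"""Parse OWL documents and extract the raw quantities the quality metrics consume.

The scoring pipeline never touches RDF directly: this module reduces an OWL
document (RDF/XML, Turtle, or functional syntax) to an
:class:`OntologyDocument` carrying

* named entities by kind (classes, properties, individuals),
* a flat list of logical axiom records with the construct categories and
  entity references of each axiom,
* the annotation surface strings (labels, comments/definitions),
* construct usage against a configurable :class:`~ontosemscore.inventory.FeatureInventory`,
* referenced namespaces, split into the ontology's own and external ones.

Logical axioms are the axiom universe for the lawfulness score; annotation
assertions and entity declarations contribute construct usage but are not
counted as logical axioms, since standards violations are defined against
logical structure.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS, XSD

from . import inventory as inv
from ._functional import parse_functional
from .errors import (
    InternalConsistencyError,
    OntologyLoadError,
    OntologyParseError,
)
from .inventory import DEFAULT_INVENTORY, FeatureInventory

logger = logging.getLogger(__name__)

ENTITY_KINDS = (
    "class",
    "object_property",
    "data_property",
    "annotation_property",
    "individual",
)

_DECLARATION_TYPES = {
    OWL.Class: "class",
    OWL.ObjectProperty: "object_property",
    OWL.DatatypeProperty: "data_property",
    OWL.AnnotationProperty: "annotation_property",
    OWL.NamedIndividual: "individual",
}

_DECLARATION_CONSTRUCTS = {
    "object_property": inv.OBJECT_PROPERTY_DECLARATION,
    "data_property": inv.DATA_PROPERTY_DECLARATION,
    "annotation_property": inv.ANNOTATION_PROPERTY_DECLARATION,
}

_CHARACTERISTIC_TYPES = {
    OWL.FunctionalProperty: inv.FUNCTIONAL_PROPERTY,
    OWL.TransitiveProperty: inv.TRANSITIVE_PROPERTY,
    OWL.SymmetricProperty: inv.SYMMETRIC_PROPERTY,
}

# Namespaces belonging to the modelling vocabulary itself; references into
# them are neither "external links" nor candidates for undeclared-entity
# violations.
BUILTIN_NAMESPACES = tuple(str(ns) for ns in (OWL, RDF, RDFS, XSD, SKOS))

_LABEL_PREDICATES = (RDFS.label,)
_COMMENT_PREDICATES = (RDFS.comment, SKOS.definition)

_FORMAT_BY_SUFFIX = {
    ".ttl": "turtle",
    ".turtle": "turtle",
    ".nt": "nt",
    ".owl": "xml",
    ".rdf": "xml",
    ".xml": "xml",
    ".ofn": "functional",
    ".ofs": "functional",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_CAMEL_LOWER_UPPER = re.compile(r"([a-z0-9])([A-Z])")
_CAMEL_ACRONYM = re.compile(r"([A-Z]+)([A-Z][a-z])")
_NON_WORD = re.compile(r"[^\w\s]+")
_SEPARATORS = re.compile(r"[_\-]+")


def normalize_surface(surface: str) -> tuple[str, ...]:
    """Normalize a surface string into lowercase tokens.

    Splits on camelCase boundaries, underscores and hyphens, strips
    punctuation, lowercases and collapses whitespace.  Idempotent: applying
    it to the joined token sequence yields the same tokens.
    """
    s = _CAMEL_LOWER_UPPER.sub(r"\1 \2", surface)
    s = _CAMEL_ACRONYM.sub(r"\1 \2", s)
    s = _SEPARATORS.sub(" ", s)
    s = _NON_WORD.sub(" ", s)
    return tuple(s.lower().split())


@dataclass(frozen=True)
class Term:
    """A surface term attached to a named entity."""

    surface: str
    normalized: tuple[str, ...]
    source_entity_kind: str  # "class" | "property" | "individual"
    provenance: str  # "label-annotation" | "iri-fragment"

    @property
    def key(self) -> tuple[str, ...]:
        """Normalized identity used for duplicate detection."""
        return self.normalized


@dataclass(frozen=True)
class ElementCounts:
    """Counts of the three element kinds a repository reports per ontology."""

    classes: int = 0
    instances: int = 0
    properties: int = 0

    def __post_init__(self) -> None:
        for name in ("classes", "instances", "properties"):
            if getattr(self, name) < 0:
                raise InternalConsistencyError(f"{name} count is negative")

    def total(self) -> int:
        return self.classes + self.instances + self.properties


@dataclass(frozen=True)
class Violation:
    axiom_id: str
    rule: str
    message: str


@dataclass(frozen=True)
class ViolationReport:
    total_axioms: int
    violations: tuple[Violation, ...] = ()

    @property
    def violating_axioms(self) -> int:
        return len({v.axiom_id for v in self.violations})

    def __post_init__(self) -> None:
        if self.total_axioms < 0:
            raise InternalConsistencyError("total_axioms is negative")
        if self.violating_axioms > self.total_axioms:
            raise InternalConsistencyError(
                "more violating axioms than axioms in total"
            )


@dataclass(frozen=True)
class Axiom:
    """A logical axiom record.

    ``constructs`` lists the construct categories the axiom exercises (a
    subclass axiom whose superclass is an existential restriction exercises
    both ``subclass-of`` and ``existential-restriction``); ``entity_refs``
    lists every named IRI the axiom mentions in an entity position.
    """

    axiom_id: str
    kind: str
    constructs: frozenset[str]
    entity_refs: frozenset[str]
    literals: tuple[Literal, ...] = ()


@dataclass
class OntologyDocument:
    iri: str
    axioms: tuple[Axiom, ...] = ()
    entities: dict[str, frozenset[str]] = field(default_factory=dict)
    annotations: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    annotation_constructs: frozenset[str] = frozenset()
    inventory: FeatureInventory = DEFAULT_INVENTORY

    def __post_init__(self) -> None:
        for kind in ENTITY_KINDS:
            self.entities.setdefault(kind, frozenset())

    # -- derived quantities -------------------------------------------------

    @property
    def logical_axiom_count(self) -> int:
        return len(self.axioms)

    @property
    def declared_entities(self) -> frozenset[str]:
        out: set[str] = set()
        for kind in ENTITY_KINDS:
            out |= self.entities[kind]
        return frozenset(out)

    @property
    def raw_construct_usage(self) -> frozenset[str]:
        used: set[str] = set(self.annotation_constructs)
        for axiom in self.axioms:
            used |= axiom.constructs
        for kind, construct in _DECLARATION_CONSTRUCTS.items():
            if self.entities[kind]:
                used.add(construct)
        return frozenset(used)

    @property
    def construct_usage(self) -> frozenset[str]:
        used = self.raw_construct_usage
        outside = used - set(self.inventory.constructs)
        if outside:
            logger.debug(
                "ontology %s uses constructs outside the inventory: %s",
                self.iri,
                sorted(outside),
            )
        return frozenset(used & set(self.inventory.constructs))

    @property
    def referenced_entities(self) -> frozenset[str]:
        refs: set[str] = set(self.declared_entities)
        for axiom in self.axioms:
            refs |= axiom.entity_refs
        refs |= set(self.annotations)
        return frozenset(refs)

    def _own_namespace(self, ns: str) -> bool:
        return ns.rstrip("#/") == self.iri.rstrip("#/")

    @property
    def referenced_namespaces(self) -> frozenset[str]:
        return frozenset(namespace_of(iri) for iri in self.referenced_entities)

    @property
    def external_namespace_refs(self) -> frozenset[str]:
        return frozenset(
            ns
            for ns in self.referenced_namespaces
            if not self._own_namespace(ns)
            and not any(ns.startswith(b) for b in BUILTIN_NAMESPACES)
        )


def namespace_of(iri: str) -> str:
    """Namespace of an IRI: everything up to and including the last '#' or '/'."""
    for sep in ("#", "/"):
        if sep in iri:
            return iri.rsplit(sep, 1)[0] + sep
    return iri


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_ontology(
    path: str | Path,
    format_hint: str | None = None,
    inventory: FeatureInventory = DEFAULT_INVENTORY,
) -> OntologyDocument:
    """Load an OWL document from ``path`` and extract its raw quantities.

    ``format_hint`` may name a serialization ("turtle", "xml",
    "functional"); otherwise the file suffix decides.
    """
    path = Path(path)
    fmt = format_hint or _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise OntologyLoadError(
            f"cannot determine serialization of {path} (pass format_hint)"
        )
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OntologyLoadError(f"cannot read ontology file {path}: {exc}") from exc
    return load_ontology_text(text, fmt, inventory=inventory, source=str(path))


def load_ontology_text(
    text: str,
    fmt: str,
    inventory: FeatureInventory = DEFAULT_INVENTORY,
    source: str = "<string>",
) -> OntologyDocument:
    """Parse ontology ``text`` in serialization ``fmt`` into a document."""
    if fmt == "functional":
        graph, ontology_iri = parse_functional(text)
    else:
        graph = Graph()
        try:
            graph.parse(data=text, format=fmt)
        except Exception as exc:  # rdflib raises many parser-specific errors
            raise OntologyParseError(f"cannot parse {source} as {fmt}: {exc}") from exc
        ontology_iri = None
    return document_from_graph(graph, inventory=inventory, ontology_iri=ontology_iri)


def document_from_graph(
    graph: Graph,
    inventory: FeatureInventory = DEFAULT_INVENTORY,
    ontology_iri: str | None = None,
) -> OntologyDocument:
    """Reduce an RDF graph (the OWL RDF mapping) to an OntologyDocument."""
    if ontology_iri is None:
        for s in graph.subjects(RDF.type, OWL.Ontology):
            if isinstance(s, URIRef):
                ontology_iri = str(s)
                break
    if ontology_iri is None:
        ontology_iri = "urn:ontosemscore:anonymous"

    # --- entity declarations, with kind disjointness by priority -----------
    entities: dict[str, set[str]] = {kind: set() for kind in ENTITY_KINDS}
    seen: dict[str, str] = {}
    for rdf_type, kind in _DECLARATION_TYPES.items():
        for s in graph.subjects(RDF.type, rdf_type):
            if not isinstance(s, URIRef):
                continue
            iri = str(s)
            if iri in seen and seen[iri] != kind:
                logger.warning(
                    "entity %s declared as both %s and %s; keeping %s",
                    iri, seen[iri], kind, seen[iri],
                )
                continue
            seen[iri] = kind
            entities[kind].add(iri)

    declared_classes = entities["class"]

    # --- axioms ------------------------------------------------------------
    axioms: list[Axiom] = []
    annotations: dict[str, dict[str, list[str]]] = defaultdict(lambda: defaultdict(list))
    annotation_constructs: set[str] = set()

    def expression(node):
        """Resolve a class-expression node → (constructs, refs, canonical id)."""
        if isinstance(node, URIRef):
            return frozenset(), frozenset({str(node)}), str(node)
        constructs: set[str] = set()
        refs: set[str] = set()
        parts: list[str] = ["restriction"]
        prop = graph.value(node, OWL.onProperty)
        if isinstance(prop, URIRef):
            refs.add(str(prop))
            parts.append(str(prop))
        for pred, construct in (
            (OWL.someValuesFrom, inv.EXISTENTIAL_RESTRICTION),
            (OWL.allValuesFrom, inv.UNIVERSAL_RESTRICTION),
        ):
            filler = graph.value(node, pred)
            if filler is not None:
                constructs.add(construct)
                parts.append(construct)
                if isinstance(filler, URIRef):
                    refs.add(str(filler))
                    parts.append(str(filler))
        for pred in (
            OWL.cardinality, OWL.minCardinality, OWL.maxCardinality,
            OWL.qualifiedCardinality, OWL.minQualifiedCardinality,
            OWL.maxQualifiedCardinality,
        ):
            value = graph.value(node, pred)
            if value is not None:
                constructs.add(inv.CARDINALITY_RESTRICTION)
                parts.append(f"{pred}={value}")
        on_class = graph.value(node, OWL.onClass)
        if isinstance(on_class, URIRef):
            refs.add(str(on_class))
            parts.append(str(on_class))
        return frozenset(constructs), frozenset(refs), "|".join(parts)

    def add_axiom(kind, subject, obj, extra_constructs=frozenset(), literals=()):
        sub_constructs, sub_refs, sub_id = expression(subject)
        obj_constructs, obj_refs, obj_id = (
            expression(obj) if obj is not None else (frozenset(), frozenset(), "")
        )
        axioms.append(
            Axiom(
                axiom_id=f"{kind}|{sub_id}|{obj_id}",
                kind=kind,
                constructs=frozenset({kind} if kind in DEFAULT_INVENTORY else set())
                | sub_constructs | obj_constructs | extra_constructs,
                entity_refs=sub_refs | obj_refs,
                literals=tuple(literals),
            )
        )

    object_props = {URIRef(i) for i in entities["object_property"]}
    data_props = {URIRef(i) for i in entities["data_property"]}
    annot_props = {URIRef(i) for i in entities["annotation_property"]}

    for s, p, o in graph:
        if p == RDFS.subClassOf:
            add_axiom(inv.SUBCLASS_OF, s, o)
        elif p == OWL.equivalentClass:
            add_axiom(inv.EQUIVALENT_CLASSES, s, o)
        elif p == OWL.disjointWith:
            add_axiom(inv.DISJOINT_CLASSES, s, o)
        elif p == RDFS.domain:
            add_axiom(inv.PROPERTY_DOMAIN, s, o)
        elif p == RDFS.range:
            add_axiom(inv.PROPERTY_RANGE, s, o)
        elif p == OWL.inverseOf:
            add_axiom(inv.INVERSE_OF, s, o)
        elif p == RDFS.subPropertyOf:
            add_axiom(inv.SUB_PROPERTY_OF, s, o)
        elif p in (OWL.sameAs, OWL.differentFrom):
            add_axiom(inv.INDIVIDUAL_IDENTITY, s, o)
        elif p == RDF.type:
            if o in _CHARACTERISTIC_TYPES:
                construct = _CHARACTERISTIC_TYPES[o]
                add_axiom(construct, s, None, extra_constructs={construct})
            elif (
                isinstance(o, URIRef)
                and not any(str(o).startswith(b) for b in BUILTIN_NAMESPACES)
            ):
                # a typing with a (possibly undeclared) user class
                add_axiom(inv.CLASS_ASSERTION, s, o)
        elif p in _LABEL_PREDICATES and isinstance(s, URIRef):
            annotations[str(s)]["label"].append(str(o))
            annotation_constructs.add(inv.LABEL_ANNOTATION)
        elif p in _COMMENT_PREDICATES and isinstance(s, URIRef):
            annotations[str(s)]["comment"].append(str(o))
            annotation_constructs.add(inv.COMMENT_ANNOTATION)
        elif p in object_props and isinstance(s, URIRef):
            axioms.append(
                Axiom(
                    axiom_id=f"object-property-assertion|{s}|{p}|{o}",
                    kind="object-property-assertion",
                    constructs=frozenset(),
                    entity_refs=frozenset({str(s), str(p)})
                    | ({str(o)} if isinstance(o, URIRef) else set()),
                )
            )
        elif p in data_props and isinstance(s, URIRef):
            axioms.append(
                Axiom(
                    axiom_id=f"data-property-assertion|{s}|{p}|{o}",
                    kind="data-property-assertion",
                    constructs=frozenset(),
                    entity_refs=frozenset({str(s), str(p)}),
                    literals=(o,) if isinstance(o, Literal) else (),
                )
            )
        elif p in annot_props and isinstance(s, URIRef):
            annotations[str(s)]["other"].append(str(o))

    # deterministic order and stable ids regardless of triple iteration order
    axioms.sort(key=lambda a: a.axiom_id)

    frozen_annotations = {
        entity: {kind: tuple(sorted(values)) for kind, values in kinds.items()}
        for entity, kinds in annotations.items()
    }
    return OntologyDocument(
        iri=ontology_iri,
        axioms=tuple(axioms),
        entities={k: frozenset(v) for k, v in entities.items()},
        annotations=frozen_annotations,
        annotation_constructs=frozenset(annotation_constructs),
        inventory=inventory,
    )


# ---------------------------------------------------------------------------
# Extraction operations
# ---------------------------------------------------------------------------

_TERM_KIND = {
    "class": "class",
    "object_property": "property",
    "data_property": "property",
    "annotation_property": "property",
    "individual": "individual",
}


def iri_fragment(iri: str) -> str:
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


def extract_terms(doc: OntologyDocument) -> list[Term]:
    """One term per named entity: label annotation preferred, IRI fragment fallback.

    Entities with neither a usable label nor a usable IRI fragment are
    skipped (and logged), never fatal.
    """
    terms: list[Term] = []
    for kind in ENTITY_KINDS:
        for iri in sorted(doc.entities[kind]):
            labels = doc.annotations.get(iri, {}).get("label", ())
            if labels:
                surface, provenance = labels[0], "label-annotation"
            else:
                surface, provenance = iri_fragment(iri), "iri-fragment"
            normalized = normalize_surface(surface)
            if not normalized:
                logger.warning("entity %s has no usable label or IRI fragment", iri)
                continue
            terms.append(
                Term(
                    surface=surface,
                    normalized=normalized,
                    source_entity_kind=_TERM_KIND[kind],
                    provenance=provenance,
                )
            )
    return terms


def count_elements(doc: OntologyDocument) -> ElementCounts:
    """Classes, instances and properties of the document (all property kinds)."""
    return ElementCounts(
        classes=len(doc.entities["class"]),
        instances=len(doc.entities["individual"]),
        properties=len(doc.entities["object_property"])
        + len(doc.entities["data_property"])
        + len(doc.entities["annotation_property"]),
    )


def feature_usage(
    doc: OntologyDocument, inventory: FeatureInventory | None = None
) -> tuple[frozenset[str], int]:
    """Constructs used from the inventory, and the inventory size."""
    inventory = inventory or doc.inventory
    used = doc.raw_construct_usage
    outside = used - set(inventory.constructs)
    if outside:
        logger.debug("constructs outside inventory ignored: %s", sorted(outside))
    return frozenset(used & set(inventory.constructs)), inventory.size


# ---------------------------------------------------------------------------
# Default validator
# ---------------------------------------------------------------------------

RULE_UNDECLARED = "undeclared-entity-reference"
RULE_RESERVED = "reserved-vocabulary-misuse"
RULE_MALFORMED_LITERAL = "malformed-literal"
RULE_VALIDATOR_ERROR = "validator-error"

# Built-in individuals/classes that are legitimate axiom references.
_WELL_KNOWN = {str(OWL.Thing), str(OWL.Nothing), str(RDFS.Literal)}


def default_validator(doc: OntologyDocument) -> list[Violation]:
    """Structural OWL checks: undeclared references, reserved-vocabulary
    misuse, malformed typed literals.

    The validator is a plain ``document -> [Violation]`` contract, so an
    external OWL 2 profile checker can be substituted for it.
    """
    declared = doc.declared_entities | _WELL_KNOWN
    violations: list[Violation] = []
    for axiom in doc.axioms:
        try:
            for ref in sorted(axiom.entity_refs):
                if any(ref.startswith(b) for b in BUILTIN_NAMESPACES):
                    # modelling-vocabulary references in object position are
                    # legitimate; subject-position misuse is caught below
                    continue
                if ref not in declared:
                    violations.append(
                        Violation(
                            axiom_id=axiom.axiom_id,
                            rule=RULE_UNDECLARED,
                            message=f"axiom references undeclared entity {ref}",
                        )
                    )
            subject = axiom.axiom_id.split("|", 2)[1]
            if (
                any(subject.startswith(b) for b in BUILTIN_NAMESPACES)
                and subject not in _WELL_KNOWN
            ):
                violations.append(
                    Violation(
                        axiom_id=axiom.axiom_id,
                        rule=RULE_RESERVED,
                        message=f"axiom re-defines reserved vocabulary {subject}",
                    )
                )
            for literal in axiom.literals:
                if getattr(literal, "ill_typed", False):
                    violations.append(
                        Violation(
                            axiom_id=axiom.axiom_id,
                            rule=RULE_MALFORMED_LITERAL,
                            message=f"ill-typed literal {literal!r}",
                        )
                    )
        except Exception as exc:  # noqa: BLE001 - recorded, never fatal
            violations.append(
                Violation(
                    axiom_id=axiom.axiom_id,
                    rule=RULE_VALIDATOR_ERROR,
                    message=str(exc),
                )
            )
    return violations


def detect_violations(doc: OntologyDocument, validator=default_validator) -> ViolationReport:
    """Run ``validator`` over the document's logical axioms.

    Deterministic: the same document and validator always yield an
    identical report.
    """
    violations = tuple(
        sorted(validator(doc), key=lambda v: (v.axiom_id, v.rule, v.message))
    )
    return ViolationReport(
        total_axioms=doc.logical_axiom_count, violations=violations
    )
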