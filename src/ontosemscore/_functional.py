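"""Minimal reader for OWL 2 functional-style syntax.

Translates a functional-syntax document into an ``rdflib.Graph`` carrying the
standard RDF mapping of the supported axiom subset, so that the rest of the
package has a single extraction path regardless of input serialization.

Supported: Prefix declarations, entity Declarations, SubClassOf,
EquivalentClasses, DisjointClasses, property hierarchy / domain / range /
inverse / characteristic axioms, ClassAssertion, SameIndividual,
DifferentIndividuals, property assertions, AnnotationAssertion, and the
ObjectSomeValuesFrom / ObjectAllValuesFrom / cardinality class expressions.
Axiom types outside this subset are skipped with a warning — they do not
abort the load.
"""

from __future__ import annotations

import logging
import re

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import OntologyParseError

logger = logging.getLogger(__name__)

_TOKEN = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<iri><[^<>\s]*>)
  | (?P<string>"(?:[^"\\]|\\.)*")
  | (?P<dtype>\^\^)
  | (?P<lang>@[A-Za-z][A-Za-z0-9-]*)
  | (?P<lpar>\() | (?P<rpar>\)) | (?P<eq>=)
  | (?P<name>[^\s()="<>@^]+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise OntologyParseError(
                f"functional syntax: unexpected character {text[pos]!r} at offset {pos}"
            )
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser producing nested ``(head, args...)`` tuples."""

    def __init__(self, tokens: list[tuple[str, str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, "", -1)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def at_end(self) -> bool:
        return self.i >= len(self.tokens)

    def parse_term(self):
        kind, value, pos = self.next()
        if kind == "name" and self.peek()[0] == "lpar":
            self.next()  # consume '('
            args = []
            while self.peek()[0] != "rpar":
                if self.at_end():
                    raise OntologyParseError(
                        f"functional syntax: unbalanced parentheses near offset {pos}"
                    )
                if self.peek()[0] == "eq":  # Prefix(p:=<iri>)
                    self.next()
                    continue
                args.append(self.parse_term())
            self.next()  # consume ')'
            return (value, *args)
        if kind == "string":
            literal = value[1:-1].replace('\\"', '"').replace("\\\\", "\\")
            nxt = self.peek()
            if nxt[0] == "dtype":
                self.next()
                dtype = self.parse_term()
                return ("@literal", literal, dtype, None)
            if nxt[0] == "lang":
                self.next()
                return ("@literal", literal, None, nxt[1][1:])
            return ("@literal", literal, None, None)
        if kind in ("iri", "name"):
            return value
        raise OntologyParseError(
            f"functional syntax: unexpected token {value!r} at offset {pos}"
        )

    def parse_document(self):
        forms = []
        while not self.at_end():
            forms.append(self.parse_term())
        return forms


_DECL_TYPES = {
    "Class": OWL.Class,
    "ObjectProperty": OWL.ObjectProperty,
    "DataProperty": OWL.DatatypeProperty,
    "AnnotationProperty": OWL.AnnotationProperty,
    "NamedIndividual": OWL.NamedIndividual,
    "Datatype": RDFS.Datatype,
}

_CHARACTERISTICS = {
    "FunctionalObjectProperty": OWL.FunctionalProperty,
    "FunctionalDataProperty": OWL.FunctionalProperty,
    "TransitiveObjectProperty": OWL.TransitiveProperty,
    "SymmetricObjectProperty": OWL.SymmetricProperty,
}


class _Converter:
    def __init__(self) -> None:
        self.graph = Graph()
        self.prefixes: dict[str, str] = {
            "owl:": str(OWL),
            "rdf:": str(RDF),
            "rdfs:": str(RDFS),
            "xsd:": str(XSD),
        }
        self.ontology_iri: str | None = None

    def resolve(self, name) -> URIRef:
        if isinstance(name, tuple):
            raise OntologyParseError(f"expected an entity, got expression {name[0]!r}")
        if name.startswith("<") and name.endswith(">"):
            return URIRef(name[1:-1])
        for prefix, base in self.prefixes.items():
            if name.startswith(prefix):
                return URIRef(base + name[len(prefix):])
        raise OntologyParseError(f"functional syntax: unresolvable name {name!r}")

    def literal(self, form) -> Literal:
        _, lexical, dtype, lang = form
        if dtype is not None:
            return Literal(lexical, datatype=self.resolve(dtype))
        if lang is not None:
            return Literal(lexical, lang=lang)
        return Literal(lexical)

    def class_expression(self, form):
        """Return an rdflib node for a class expression, adding bnode triples."""
        if not isinstance(form, tuple):
            return self.resolve(form)
        head = form[0]
        node = BNode()
        g = self.graph
        g.add((node, RDF.type, OWL.Restriction))
        if head == "ObjectSomeValuesFrom":
            g.add((node, OWL.onProperty, self.resolve(form[1])))
            g.add((node, OWL.someValuesFrom, self.class_expression(form[2])))
        elif head == "ObjectAllValuesFrom":
            g.add((node, OWL.onProperty, self.resolve(form[1])))
            g.add((node, OWL.allValuesFrom, self.class_expression(form[2])))
        elif head in ("ObjectMinCardinality", "ObjectMaxCardinality", "ObjectExactCardinality"):
            pred = {
                "ObjectMinCardinality": OWL.minCardinality,
                "ObjectMaxCardinality": OWL.maxCardinality,
                "ObjectExactCardinality": OWL.cardinality,
            }[head]
            g.add((node, pred, Literal(int(form[1]), datatype=XSD.nonNegativeInteger)))
            g.add((node, OWL.onProperty, self.resolve(form[2])))
        else:
            raise OntologyParseError(
                f"functional syntax: unsupported class expression {head!r}"
            )
        return node

    def convert(self, forms) -> Graph:
        for form in forms:
            if not isinstance(form, tuple):
                continue
            head = form[0]
            if head == "Prefix":
                # args: name(":"-terminated prefix), <iri>
                prefix, iri = form[1], form[2]
                self.prefixes[prefix] = iri[1:-1] if iri.startswith("<") else iri
            elif head == "Ontology":
                args = list(form[1:])
                if args and not isinstance(args[0], tuple):
                    self.ontology_iri = str(self.resolve(args[0]))
                    self.graph.add(
                        (URIRef(self.ontology_iri), RDF.type, OWL.Ontology)
                    )
                    args = args[1:]
                    # optional version IRI
                    if args and not isinstance(args[0], tuple):
                        args = args[1:]
                for axiom in args:
                    self.axiom(axiom)
            else:
                self.axiom(form)
        return self.graph

    def axiom(self, form) -> None:
        if not isinstance(form, tuple):
            logger.warning("functional syntax: ignoring stray token %r", form)
            return
        head = form[0]
        g = self.graph
        try:
            if head == "Declaration":
                inner = form[1]
                decl_type = _DECL_TYPES.get(inner[0])
                if decl_type is None:
                    logger.warning("ignoring declaration of kind %r", inner[0])
                    return
                g.add((self.resolve(inner[1]), RDF.type, decl_type))
            elif head == "SubClassOf":
                g.add(
                    (
                        self.class_expression(form[1]),
                        RDFS.subClassOf,
                        self.class_expression(form[2]),
                    )
                )
            elif head == "EquivalentClasses":
                exprs = [self.class_expression(a) for a in form[1:]]
                for a, b in zip(exprs, exprs[1:]):
                    g.add((a, OWL.equivalentClass, b))
            elif head == "DisjointClasses":
                exprs = [self.class_expression(a) for a in form[1:]]
                for a, b in zip(exprs, exprs[1:]):
                    g.add((a, OWL.disjointWith, b))
            elif head in ("SubObjectPropertyOf", "SubDataPropertyOf", "SubAnnotationPropertyOf"):
                g.add((self.resolve(form[1]), RDFS.subPropertyOf, self.resolve(form[2])))
            elif head in ("ObjectPropertyDomain", "DataPropertyDomain", "AnnotationPropertyDomain"):
                g.add((self.resolve(form[1]), RDFS.domain, self.class_expression(form[2])))
            elif head in ("ObjectPropertyRange", "DataPropertyRange", "AnnotationPropertyRange"):
                g.add((self.resolve(form[1]), RDFS.range, self.class_expression(form[2])))
            elif head == "InverseObjectProperties":
                g.add((self.resolve(form[1]), OWL.inverseOf, self.resolve(form[2])))
            elif head in _CHARACTERISTICS:
                g.add((self.resolve(form[1]), RDF.type, _CHARACTERISTICS[head]))
            elif head == "ClassAssertion":
                g.add((self.resolve(form[2]), RDF.type, self.class_expression(form[1])))
            elif head == "SameIndividual":
                nodes = [self.resolve(a) for a in form[1:]]
                for a, b in zip(nodes, nodes[1:]):
                    g.add((a, OWL.sameAs, b))
            elif head == "DifferentIndividuals":
                nodes = [self.resolve(a) for a in form[1:]]
                for a, b in zip(nodes, nodes[1:]):
                    g.add((a, OWL.differentFrom, b))
            elif head == "ObjectPropertyAssertion":
                g.add((self.resolve(form[2]), self.resolve(form[1]), self.resolve(form[3])))
            elif head == "DataPropertyAssertion":
                g.add((self.resolve(form[2]), self.resolve(form[1]), self.literal(form[3])))
            elif head == "AnnotationAssertion":
                prop = self.resolve(form[1])
                subject = self.resolve(form[2])
                value = self.literal(form[3]) if isinstance(form[3], tuple) else self.resolve(form[3])
                g.add((subject, prop, value))
            else:
                logger.warning("functional syntax: skipping unsupported axiom %r", head)
        except (IndexError, TypeError) as exc:
            raise OntologyParseError(
                f"functional syntax: malformed {head!r} axiom"
            ) from exc


def parse_functional(text: str) -> tuple[Graph, str | None]:
    """Parse functional-syntax text into (graph, ontology IRI)."""
    converter = _Converter()
    graph = converter.convert(_Parser(_tokenize(text)).parse_document())
    return graph, converter.ontology_iri
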