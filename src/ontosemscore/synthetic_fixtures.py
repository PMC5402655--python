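"""Synthetic OWL ontologies with analytically known expected sub-scores.

The generator turns a :class:`FixtureSpec` into a small OWL document (Turtle
or RDF/XML) whose lawfulness, richness, interpretability, consistency and
clarity are implied in closed form by the spec itself — independent integer
arithmetic, no call into the scoring code.  Corpora of such fixtures make
every corpus-relative score testable without downloading anything.

Construction rules (all deterministic given the spec and its seed):

* classes are declared in a fixed order — lexicon-labelled first (duplicate
  labels expand into extra classes sharing the label), then
  gibberish-labelled ones whose labels are seeded random strings guaranteed
  absent from any lexicon;
* object properties are lexicon-labelled; individuals carry no label and
  fall back to their (digit-bearing, hence never interpretable) IRI names;
* each requested construct contributes a fixed, countable set of axioms
  (e.g. ``subclass-of`` builds a class chain of n−1 axioms);
* violations are injected as subclass axioms referencing undeclared
  classes, one per violating axiom, so the default validator's count is
  exact by construction.

Fixture vocabulary should be drawn from the bundled mini-lexicon so that
semantic scores do not depend on any external lexical resource.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from . import inventory as inv
from .errors import FixtureSpecError
from .lexicon import WordSenseLexicon
from .subscores import SubScores

_GIBBERISH_ALPHABET = "bcdfghjklmnpqrstvw"

_RESTRICTIONS = frozenset(
    {inv.EXISTENTIAL_RESTRICTION, inv.UNIVERSAL_RESTRICTION, inv.CARDINALITY_RESTRICTION}
)
_NEEDS_ONE_PROPERTY = _RESTRICTIONS | frozenset(
    {
        inv.OBJECT_PROPERTY_DECLARATION,
        inv.PROPERTY_DOMAIN,
        inv.PROPERTY_RANGE,
        inv.FUNCTIONAL_PROPERTY,
        inv.TRANSITIVE_PROPERTY,
        inv.SYMMETRIC_PROPERTY,
    }
)
_NEEDS_TWO_PROPERTIES = frozenset({inv.INVERSE_OF, inv.SUB_PROPERTY_OF})


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic ontology."""

    ontology_id: str
    lexical_class_labels: tuple[tuple[str, int], ...] = ()
    gibberish_classes: int = 0
    duplicate_label_multiplicity: Mapping[str, int] = field(default_factory=dict)
    property_labels: tuple[tuple[str, int], ...] = ()
    n_individuals: int = 0
    constructs: frozenset[str] = frozenset({inv.SUBCLASS_OF, inv.LABEL_ANNOTATION})
    violation_count: int = 0
    seed: int = 0

    # -- derived sizes ------------------------------------------------------

    @property
    def n_classes(self) -> int:
        extra = sum(m - 1 for m in self.duplicate_label_multiplicity.values())
        return len(self.lexical_class_labels) + self.gibberish_classes + extra

    @property
    def n_properties(self) -> int:
        return len(self.property_labels)

    def validate(self, inventory=inv.DEFAULT_INVENTORY) -> None:
        c = self.constructs
        if not c <= set(inventory.constructs):
            raise FixtureSpecError(
                f"constructs outside the inventory: {sorted(c - set(inventory.constructs))}"
            )
        lemmas = [lemma for lemma, _ in self.lexical_class_labels]
        if len(set(lemmas)) != len(lemmas):
            raise FixtureSpecError("lexical class lemmas must be distinct")
        prop_lemmas = [lemma for lemma, _ in self.property_labels]
        if len(set(prop_lemmas)) != len(prop_lemmas) or set(prop_lemmas) & set(lemmas):
            raise FixtureSpecError("property lemmas must be distinct from class lemmas")
        for lemma, mult in self.duplicate_label_multiplicity.items():
            if lemma not in lemmas:
                raise FixtureSpecError(f"duplicate target {lemma!r} is not a class label")
            if mult < 1:
                raise FixtureSpecError("duplicate multiplicity must be >= 1")
        if (self.lexical_class_labels or self.gibberish_classes or prop_lemmas) \
                and inv.LABEL_ANNOTATION not in c:
            raise FixtureSpecError("labelled fixtures require the label-annotation construct")
        if self.violation_count > 0 and inv.SUBCLASS_OF not in c:
            raise FixtureSpecError("injected violations require the subclass-of construct")
        if c & _RESTRICTIONS and inv.SUBCLASS_OF not in c:
            raise FixtureSpecError("restrictions are attached via subclass-of")
        if inv.SUBCLASS_OF in c and self.n_classes < 2:
            raise FixtureSpecError("subclass-of chain needs at least two classes")
        if c & {inv.EQUIVALENT_CLASSES, inv.DISJOINT_CLASSES} and self.n_classes < 2:
            raise FixtureSpecError("class axioms need at least two classes")
        if c & _NEEDS_ONE_PROPERTY and self.n_properties < 1:
            raise FixtureSpecError("property constructs need at least one property")
        if self.n_properties >= 1 and inv.OBJECT_PROPERTY_DECLARATION not in c:
            raise FixtureSpecError(
                "properties imply the object-property-declaration construct"
            )
        if c & _NEEDS_TWO_PROPERTIES and self.n_properties < 2:
            raise FixtureSpecError("inverse/sub-property constructs need two properties")
        if inv.CLASS_ASSERTION in c and (self.n_individuals < 1 or self.n_classes < 1):
            raise FixtureSpecError("class assertions need an individual and a class")
        if inv.INDIVIDUAL_IDENTITY in c and self.n_individuals < 2:
            raise FixtureSpecError("individual identity needs two individuals")
        if self.violation_count > self.expected_axiom_count():
            raise FixtureSpecError("violations exceed the resulting axiom count")

    # -- closed-form expectations ------------------------------------------

    def expected_axiom_count(self) -> int:
        c = self.constructs
        count = 0
        if inv.SUBCLASS_OF in c:
            count += self.n_classes - 1
        for construct in (
            inv.EQUIVALENT_CLASSES,
            inv.DISJOINT_CLASSES,
            inv.PROPERTY_DOMAIN,
            inv.PROPERTY_RANGE,
            inv.INVERSE_OF,
            inv.SUB_PROPERTY_OF,
            inv.FUNCTIONAL_PROPERTY,
            inv.TRANSITIVE_PROPERTY,
            inv.SYMMETRIC_PROPERTY,
            inv.INDIVIDUAL_IDENTITY,
        ):
            if construct in c:
                count += 1
        count += len(c & _RESTRICTIONS)
        if inv.CLASS_ASSERTION in c:
            count += self.n_individuals
        count += self.violation_count
        return count

    def expected_scores(self, inventory=inv.DEFAULT_INVENTORY) -> SubScores:
        """Closed-form sub-scores implied by the spec (corpus-relative ones absent)."""
        self.validate(inventory)
        axioms = self.expected_axiom_count()
        lawfulness = 1.0 if axioms == 0 else 1.0 - self.violation_count / axioms
        richness = len(self.constructs) / inventory.size

        occurrences = self.n_classes + self.n_properties + self.n_individuals
        distinct = (
            len(self.lexical_class_labels)
            + self.gibberish_classes
            + self.n_properties
            + self.n_individuals
        )
        mult = {lemma: self.duplicate_label_multiplicity.get(lemma, 1)
                for lemma, _ in self.lexical_class_labels}
        interpretable = sum(mult.values()) + self.n_properties
        sense_total = sum(
            senses * mult[lemma] for lemma, senses in self.lexical_class_labels
        ) + sum(senses for _, senses in self.property_labels)

        if occurrences == 0:
            interp = consist = clar = None
        else:
            interp = interpretable / occurrences
            consist = 1.0 - (occurrences - distinct) / distinct
            clar = (
                1.0 if interpretable == 0
                else min(1.0, interpretable / sense_total)
            )
        return SubScores(
            lawfulness=lawfulness,
            richness=richness,
            interpretability=interp,
            consistency=consist,
            clarity=clar,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _gibberish_labels(rng: random.Random, count: int) -> list[str]:
    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < count:
        label = "zz" + "".join(rng.choice(_GIBBERISH_ALPHABET) for _ in range(6))
        if label not in seen:
            seen.add(label)
            labels.append(label)
    return labels


def build_graph(spec: FixtureSpec) -> Graph:
    """Deterministically build the RDF graph of a fixture."""
    spec.validate()
    rng = random.Random(spec.seed)
    base = f"http://example.org/synthetic/{spec.ontology_id}"
    ns = Namespace(base + "#")
    g = Graph()
    g.bind("", ns)
    g.bind("owl", OWL)
    g.add((URIRef(base), RDF.type, OWL.Ontology))

    c = spec.constructs
    labelled = inv.LABEL_ANNOTATION in c

    # classes: lexical (duplicates expanded) then gibberish
    class_labels: list[str] = []
    for lemma, _ in spec.lexical_class_labels:
        class_labels.extend(
            [lemma] * spec.duplicate_label_multiplicity.get(lemma, 1)
        )
    class_labels.extend(_gibberish_labels(rng, spec.gibberish_classes))
    classes = [ns[f"Class{i:03d}"] for i in range(1, len(class_labels) + 1)]
    for cls, label in zip(classes, class_labels):
        g.add((cls, RDF.type, OWL.Class))
        if labelled:
            g.add((cls, RDFS.label, Literal(label)))

    properties = [ns[f"prop{i:02d}"] for i in range(1, spec.n_properties + 1)]
    for prop, (lemma, _) in zip(properties, spec.property_labels):
        g.add((prop, RDF.type, OWL.ObjectProperty))
        if labelled:
            g.add((prop, RDFS.label, Literal(lemma)))

    individuals = [ns[f"Subject{i:03d}"] for i in range(1, spec.n_individuals + 1)]
    for ind in individuals:
        g.add((ind, RDF.type, OWL.NamedIndividual))

    if inv.SUBCLASS_OF in c:
        for sub, sup in zip(classes[1:], classes):
            g.add((sub, RDFS.subClassOf, sup))
    if inv.EQUIVALENT_CLASSES in c:
        g.add((classes[0], OWL.equivalentClass, classes[1]))
    if inv.DISJOINT_CLASSES in c:
        g.add((classes[-2], OWL.disjointWith, classes[-1]))
    if inv.PROPERTY_DOMAIN in c:
        g.add((properties[0], RDFS.domain, classes[0]))
    if inv.PROPERTY_RANGE in c:
        g.add((properties[0], RDFS.range, classes[-1]))
    if inv.INVERSE_OF in c:
        g.add((properties[0], OWL.inverseOf, properties[1]))
    if inv.SUB_PROPERTY_OF in c:
        g.add((properties[1], RDFS.subPropertyOf, properties[0]))
    if inv.FUNCTIONAL_PROPERTY in c:
        g.add((properties[0], RDF.type, OWL.FunctionalProperty))
    if inv.TRANSITIVE_PROPERTY in c:
        g.add((properties[0], RDF.type, OWL.TransitiveProperty))
    if inv.SYMMETRIC_PROPERTY in c:
        g.add((properties[0], RDF.type, OWL.SymmetricProperty))
    for construct, pred in (
        (inv.EXISTENTIAL_RESTRICTION, OWL.someValuesFrom),
        (inv.UNIVERSAL_RESTRICTION, OWL.allValuesFrom),
    ):
        if construct in c:
            node = BNode(f"restr_{construct.replace('-', '_')}")
            g.add((node, RDF.type, OWL.Restriction))
            g.add((node, OWL.onProperty, properties[0]))
            g.add((node, pred, classes[-1]))
            g.add((classes[0], RDFS.subClassOf, node))
    if inv.CARDINALITY_RESTRICTION in c:
        node = BNode("restr_cardinality")
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, properties[0]))
        g.add((node, OWL.minCardinality,
               Literal(1, datatype=XSD.nonNegativeInteger)))
        g.add((classes[0], RDFS.subClassOf, node))
    if inv.CLASS_ASSERTION in c:
        for ind in individuals:
            g.add((ind, RDF.type, classes[0]))
    if inv.INDIVIDUAL_IDENTITY in c:
        g.add((individuals[0], OWL.differentFrom, individuals[1]))
    if inv.COMMENT_ANNOTATION in c:
        target = classes[0] if classes else URIRef(base)
        g.add((target, RDFS.comment, Literal(f"synthetic fixture {spec.ontology_id}")))

    # injected violations: subclass axioms referencing undeclared classes
    for j in range(1, spec.violation_count + 1):
        g.add((classes[0], RDFS.subClassOf, ns[f"Undeclared{j:03d}"]))

    return g


_SUFFIX = {"turtle": ".ttl", "xml": ".owl", "pretty-xml": ".owl"}


def generate_ontology(spec: FixtureSpec, fmt: str = "turtle") -> tuple[str, SubScores]:
    """Serialize a fixture; returns (document text, expected sub-scores)."""
    if fmt not in _SUFFIX:
        raise FixtureSpecError(f"unsupported fixture serialization {fmt!r}")
    graph = build_graph(spec)
    return graph.serialize(format=fmt), spec.expected_scores()


@dataclass(frozen=True)
class CorpusManifest:
    directory: Path
    paths: dict[str, Path]
    metadata_path: Path
    expected: dict[str, SubScores]
    access_counts: dict[str, int]


def generate_corpus(
    specs: Sequence[FixtureSpec],
    access_counts: Sequence[int],
    out_dir: str | Path,
    fmt: str = "turtle",
) -> CorpusManifest:
    """Write a fixture corpus plus its metadata CSV (id, classes, instances,
    properties, accesses).  The metadata totals match the generated files by
    construction."""
    if not specs:
        raise FixtureSpecError("a corpus needs at least one member")
    if len(access_counts) != len(specs):
        raise FixtureSpecError("need one access count per corpus member")
    ids = [s.ontology_id for s in specs]
    if len(set(ids)) != len(ids):
        raise FixtureSpecError("duplicate ontology ids in corpus")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    paths: dict[str, Path] = {}
    expected: dict[str, SubScores] = {}
    rows = []
    for spec, accesses in zip(specs, access_counts):
        text, scores = generate_ontology(spec, fmt=fmt)
        path = out_dir / f"{spec.ontology_id}{_SUFFIX[fmt]}"
        path.write_text(text, encoding="utf-8")
        paths[spec.ontology_id] = path
        expected[spec.ontology_id] = scores
        rows.append(
            {
                "id": spec.ontology_id,
                "classes": spec.n_classes,
                "instances": spec.n_individuals,
                "properties": spec.n_properties,
                "accesses": int(accesses),
            }
        )
    metadata_path = out_dir / "metadata.csv"
    with metadata_path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=["id", "classes", "instances", "properties", "accesses"]
        )
        writer.writeheader()
        writer.writerows(rows)
    return CorpusManifest(
        directory=out_dir,
        paths=paths,
        metadata_path=metadata_path,
        expected=expected,
        access_counts={s.ontology_id: int(a) for s, a in zip(specs, access_counts)},
    )


# ---------------------------------------------------------------------------
# Ready-made specs
# ---------------------------------------------------------------------------

_BASE_CONSTRUCTS = frozenset(
    {
        inv.SUBCLASS_OF,
        inv.LABEL_ANNOTATION,
        inv.COMMENT_ANNOTATION,
        inv.OBJECT_PROPERTY_DECLARATION,
        inv.PROPERTY_DOMAIN,
        inv.PROPERTY_RANGE,
    }
)

_EXTRA_CONSTRUCTS = (
    inv.DISJOINT_CLASSES,
    inv.EQUIVALENT_CLASSES,
    inv.FUNCTIONAL_PROPERTY,
    inv.SYMMETRIC_PROPERTY,
    inv.TRANSITIVE_PROPERTY,
    inv.EXISTENTIAL_RESTRICTION,
)


def drug_like_corpus_specs(
    lexicon: WordSenseLexicon, seed: int = 0
) -> tuple[list[FixtureSpec], list[int]]:
    """Seven fixtures engineered so the corpus branch means, reported at two
    decimals, equal (syntactic 0.67, semantic 0.83, pragmatic 0.14,
    social 0.14) — the profile of the drug-ontology benchmark corpus.

    Each member has ten classes and one labelled object property; fixtures
    differ in how many class labels carry a word sense (4 of 10 in the first
    four members, 5 of 10 in the last three) and in one extra construct per
    member beyond a shared six-construct core.
    """
    monosemous = sorted(
        lemma for lemma, count in lexicon.entries.items()
        if count == 1 and " " not in lemma
    )
    if len(monosemous) < 12:
        raise FixtureSpecError("lexicon too small for the engineered corpus")
    specs: list[FixtureSpec] = []
    for j in range(7):
        n_lexical = 4 if j < 4 else 5
        rng = random.Random(seed * 1000 + j)
        lemmas = rng.sample(monosemous, n_lexical + 1)
        constructs = _BASE_CONSTRUCTS if j == 0 else (
            _BASE_CONSTRUCTS | {_EXTRA_CONSTRUCTS[j - 1]}
        )
        specs.append(
            FixtureSpec(
                ontology_id=f"drugfix{j + 1}",
                lexical_class_labels=tuple((lemma, 1) for lemma in lemmas[:n_lexical]),
                gibberish_classes=10 - n_lexical,
                property_labels=((lemmas[n_lexical], 1),),
                constructs=constructs,
                violation_count=0,
                seed=seed * 1000 + j,
            )
        )
    access_counts = [9600, 120, 80, 60, 40, 60, 40]
    return specs, access_counts


def random_fixture_spec(
    rng: random.Random,
    lexicon: WordSenseLexicon,
    ontology_id: str = "random",
) -> FixtureSpec:
    """A random but always-valid fixture spec over the given lexicon."""
    lemmas = sorted(lemma for lemma in lexicon.entries if " " not in lemma)
    n_lexical = rng.randint(2, 6)
    n_props = rng.randint(0, 3)
    chosen = rng.sample(lemmas, n_lexical + n_props)
    lexical = tuple((lemma, lexicon.sense_count(lemma)) for lemma in chosen[:n_lexical])
    props = tuple((lemma, lexicon.sense_count(lemma)) for lemma in chosen[n_lexical:])
    gibberish = rng.randint(0, 5)
    n_individuals = rng.randint(0, 4)

    duplicates: dict[str, int] = {}
    if rng.random() < 0.5:
        duplicates[chosen[0]] = rng.randint(2, 4)

    constructs = {inv.SUBCLASS_OF, inv.LABEL_ANNOTATION}
    pool = [inv.COMMENT_ANNOTATION, inv.EQUIVALENT_CLASSES, inv.DISJOINT_CLASSES]
    if n_props >= 1:
        constructs.add(inv.OBJECT_PROPERTY_DECLARATION)
        pool += [
            inv.PROPERTY_DOMAIN, inv.PROPERTY_RANGE, inv.FUNCTIONAL_PROPERTY,
            inv.TRANSITIVE_PROPERTY, inv.SYMMETRIC_PROPERTY,
            inv.EXISTENTIAL_RESTRICTION, inv.UNIVERSAL_RESTRICTION,
            inv.CARDINALITY_RESTRICTION,
        ]
    if n_props >= 2:
        pool += [inv.INVERSE_OF, inv.SUB_PROPERTY_OF]
    if n_individuals >= 1:
        pool.append(inv.CLASS_ASSERTION)
    if n_individuals >= 2:
        pool.append(inv.INDIVIDUAL_IDENTITY)
    constructs |= set(rng.sample(pool, rng.randint(0, len(pool))))

    return FixtureSpec(
        ontology_id=ontology_id,
        lexical_class_labels=lexical,
        gibberish_classes=gibberish,
        duplicate_label_multiplicity=duplicates,
        property_labels=props,
        n_individuals=n_individuals,
        constructs=frozenset(constructs),
        violation_count=rng.randint(0, 3),
        seed=rng.randrange(2**31),
    )
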