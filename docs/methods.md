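# Methods

## The scoring model

`ontosemscore` implements a semiotic quality metric for OWL 2 ontologies.
An ontology is reduced to raw quantities — logical axioms, named entities,
surface terms, construct usage, namespace references — and scored on ten
ratio sub-scores grouped into four branches (syntactic, semantic,
pragmatic, social). Branch scores and the overall score Q are convex
combinations under nonnegative weights; every weight group is renormalized
over the sub-scores actually present, so an absent score shifts its weight
proportionally onto its siblings instead of silently counting as zero.

The model's assumptions, in brief: quality is decomposable into
independently measurable ratios; terms (labels) are an adequate proxy for
an ontology's semantic surface; and community standing (access counts) is
meaningful only *relative to a corpus*, which is why comprehensiveness and
history are corpus-relative shares rather than absolute sizes.

## Raw extraction

* **Axiom universe.** Lawfulness is defined over *logical* axioms
  (subclass/equivalence/disjointness, property domain–range–hierarchy–
  characteristic axioms, assertions, individual identity). Annotation
  assertions and entity declarations contribute construct usage but are not
  part of the violation denominator: standards violations are a property of
  logical structure, and counting annotations would dilute the ratio on
  annotation-heavy ontologies.
* **Construct inventory.** Richness needs a fixed denominator; OWL itself
  does not define "the" feature list. The default inventory has 20
  documented construct categories (see `ontosemscore/inventory.py`),
  covering class axioms, property declarations and axioms, the three
  restriction families, ABox assertions and the two annotation kinds.
  Usage is presence-based — one use or a thousand count once — because the
  score measures vocabulary breadth, not volume. The inventory is
  configurable; changing it changes richness denominators and is recorded
  in reports.
* **Validator.** The bundled validator is structural: undeclared-entity
  references, reserved-vocabulary misuse (redefinition of OWL/RDF/RDFS
  terms), and ill-typed literals. It is a plain
  ``document -> [violation]`` contract so that a full OWL 2 profile
  checker can be dropped in; lawfulness only needs the count of distinct
  violating axioms, never the tool that produced it.
* **Terms.** One term per named entity (classes, all property kinds, named
  individuals), label annotation preferred, IRI local name as fallback.
  Normalization splits camelCase, underscores and hyphens, strips
  punctuation and lowercases; it is idempotent, so duplicate detection is
  insensitive to labeling style.

## Sub-score formulas and open choices

Some formulas are not pinned down by the framework's prose; the package
fixes a default and documents the alternative where one is plausible.

* **Lawfulness** `S_L = 1 − V/A` (violating axioms over total), vacuously 1
  for an axiom-free document.
* **Richness** `S_R = used/inventory`.
* **Interpretability** `E_I` = fraction of terms with at least one word
  sense. Multiword terms use token-level lookup: a term is interpretable if
  any *content token* (alphabetic, length ≥ 2 — so the "b" of "hepatitis b"
  never decides) has a sense, and its polysemy is the maximum over its
  tokens. Whole-phrase lexicon entries are rare for domain labels, and
  token matching is what makes high interpretability attainable for
  drug-style vocabularies. No stemming by default, for determinism.
* **Consistency** `E_C = 1 − (T − U)/U` with T term occurrences and U
  distinct normalized terms. This variant (rather than the duplicate
  fraction `1 − (T−U)/T`) is the default because it is the only one whose
  range extends below zero, which is observed on heavily duplicated real
  corpora; the milder variant is selectable via
  ``consistency_formula: duplicate-fraction``.
* **Clarity** `E_A = min(1, N/Σ senses)` — the reciprocal of mean polysemy
  over the N interpretable terms, clamped to [0, 1]; all-monosemous
  vocabularies score 1 and a mean polysemy of 7 scores ≈ 0.14. A document
  with no interpretable term is *vacuously* unambiguous (1): penalizing it
  here would double-count what interpretability already measures.
* **Comprehensiveness / history** are shares of the corpus totals of
  elements (classes+instances+properties) and access counts. Per-ontology
  counts come from a local metadata CSV (the snapshot a repository REST API
  would return, recorded with a snapshot identifier), keeping scoring
  hermetic. Over a fully scored corpus both partition to Σ = 1.
* **Accuracy / relevancy** require expert review and are injected as
  values in [0, 1]; they are never computed.
* **Authority** is the share of referenced namespaces that are neither the
  ontology's own nor modelling vocabulary. The denominator — all distinct
  referenced namespaces — is an interpretation (nothing in the framework
  fixes it); since repository metadata carries no citation graph, authority
  is excluded from default scoring (weight 0) and the social branch
  defaults to history alone.
* **Absence policy.** Semantic scores of a termless ontology, or
  corpus-relative scores without a context, are *absent*, not 0: absence
  triggers weight renormalization, a 0 would be a silent penalty.

## Aggregation and rounding

Branch scores and Q are computed at full precision; decimal half-up
rounding to two places happens only at report time. Negative consistency
propagates unclamped into the semantic branch and Q. When corpora are
compared on a shared subset of branches (e.g. syntactic+semantic only,
because the corpus-relative branches are not comparable across corpora),
the remaining weights are deliberately *not* renormalized
(``renormalize=False``), preserving each branch's 0.25 contribution.

Reproduction tests against published two-decimal tables use ±0.01
tolerances: the published inputs are themselves roundings, and whether the
original aggregation rounded before or after combining is unknowable.

## Weight modulation

Modulated branch weights are the corpus's mean branch scores divided by
their sum, rounded at two decimals by **largest-remainder apportionment**
(floor every weight at the target precision, then hand the missing
hundredths to the largest fractional remainders). Naive rounding of e.g.
means (0.67, 0.83, 0.14, 0.14) gives (0.38, **0.47**, 0.08, 0.08), which
sums to 1.01; largest-remainder yields (0.38, **0.46**, 0.08, 0.08) with an
exact total — this is the published tuple, and the reason the procedure is
part of the method rather than a formatting detail. Inputs are the corpus
means *at reporting precision* (two decimals), matching a workflow driven
from a reported score table; means are absent-as-zero, and medians are
selectable in configuration but not default. Derived weights are
nonnegative, sum to exactly 1.00 at two decimals, are scale-invariant in
the means and permutation-equivariant up to exact remainder ties (broken
deterministically by branch order). An all-zero mean vector is a
degenerate-corpus error.

Statistics tables report mean, sample (n−1) standard deviation, min, max
and median. At n = 7 the sample/population choice moves printed sds by at
most ±0.01.

## The synthetic-data generator

`synthetic_fixtures` emulates what the metric consumes, not what real
ontologies look like: small OWL documents (≈ 5–20 entities, up to ~10³ by
spec) whose sub-scores are implied in closed form by the generating spec —
labels drawn from the bundled mini-lexicon (70 frozen lemma→sense-count
entries, so no external lexical resource is needed), gibberish labels
guaranteed senseless, duplicates and undeclared-reference violations
injected in counted numbers, constructs added one countable axiom group at
a time. Scoring a generated fixture must reproduce the closed-form
expectation *exactly* (both sides are small-integer ratios), which is the
package's strongest end-to-end oracle; the acceptance script measures a max
absolute error of 0 over 100 randomized specs.

The ready-made seven-member corpus is engineered so the corpus branch
means, at reporting precision, are (0.67, 0.83, 0.14, 0.14) — ten classes
and one labelled property per member, 4-of-10 interpretable labels in four
members and 5-of-10 in three, a six-construct core plus one extra construct
in six members; the pragmatic/social means are 1/7 by the partition
property. Modulating this corpus therefore reproduces the
(0.38, 0.46, 0.08, 0.08) tuple end to end.

What passing these tests does **not** show: behavior on ontologies with
imports, anonymous class expressions beyond simple restrictions,
multilingual labels, or lexicons with phrase entries; nor anything about
absolute score levels of real repositories, which depend on the metadata
snapshot used.

## Numerical notes and limitations

* Largest-remainder flooring adds a 1e−9 guard against float floors like
  `0.29·100 → 28.999…`; if the guard ever over-floors, units are taken back
  from the smallest remainders.
* Axiom identities are canonical strings (kind + participants), so a
  violation hitting two rules counts one violating axiom and two
  violation records, and duplicate triples across serializations collapse.
* Punning (one IRI declared as two entity kinds) is resolved by a fixed
  kind priority and logged; entity sets stay disjoint.
* Imports are not resolved over the network; an imported file is scored
  only if supplied locally. OBO format and reasoning-based checks are out
  of scope.
* The functional-syntax reader covers the declaration/axiom subset the
  extractor understands and skips other axiom types with a warning.
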