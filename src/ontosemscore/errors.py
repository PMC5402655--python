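"""Exception hierarchy for ontosemscore."""


class OntoSemScoreError(Exception):
    """Base class for all package errors."""


class OntologyLoadError(OntoSemScoreError):
    """An ontology file could not be read (missing, unreadable, unknown format)."""


class OntologyParseError(OntoSemScoreError):
    """An ontology file was read but its content could not be parsed."""


class UndefinedScoreError(OntoSemScoreError):
    """A sub-score is undefined for the given input (e.g. no terms at all).

    Callers in the scoring pipeline catch this and record the score as
    *absent*, which triggers weight renormalization rather than a silent 0.
    """


class ConfigurationError(OntoSemScoreError):
    """Invalid configuration (empty inventory, zero corpus total, bad weights)."""


class ScoreValidationError(OntoSemScoreError):
    """A supplied score value is outside its admissible range."""


class InternalConsistencyError(OntoSemScoreError):
    """An internal invariant was violated (e.g. more violations than axioms)."""


class LexiconResourceError(OntoSemScoreError):
    """A lexicon backend resource is missing or unreadable."""


class FixtureSpecError(OntoSemScoreError):
    """A synthetic-fixture specification is internally inconsistent."""


class DegenerateCorpusError(OntoSemScoreError):
    """A corpus-level computation is undefined (e.g. all branch means zero)."""
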