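"""Word-sense lexicons behind a single lookup contract.

Semantic sub-scores depend on a lexicon only through
``lexicon.sense_count(lemma) -> int``: deterministic, 0 for unknown lemmas.
Two backends are provided — a bundled deterministic mini-lexicon (frozen
synthetic sense counts over a drug-flavoured vocabulary, used by all tests)
and an adapter that reads the standard WordNet database directory layout
(``index.noun`` etc.) when a local WordNet installation is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import LexiconResourceError
from .ontology_model import Term

_MINI_LEXICON_RESOURCE = "mini_lexicon.tsv"
_WORDNET_INDEX_FILES = ("index.noun", "index.verb", "index.adj", "index.adv")


@dataclass(frozen=True)
class WordSenseLexicon:
    """Immutable lemma → sense-count table."""

    entries: Mapping[str, int]
    source: str = "custom"
    version: str = "0"

    def sense_count(self, lemma: str) -> int:
        """Number of senses of ``lemma`` (expected lowercase); 0 if unknown."""
        count = self.entries.get(lemma, 0)
        return count if count > 0 else 0

    def __len__(self) -> int:
        return len(self.entries)

    def save_table(self, path: str | Path) -> None:
        """Write the lexicon as a two-column (lemma, sense_count) table."""
        lines = [f"{lemma}\t{count}" for lemma, count in sorted(self.entries.items())]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class TermSenseStats:
    """Sense statistics of one term under a lexicon."""

    term: Term
    sense_count: int

    @property
    def interpretable(self) -> bool:
        return self.sense_count >= 1


def sense_count(lemma: str, lexicon: WordSenseLexicon) -> int:
    return lexicon.sense_count(lemma)


def _content_tokens(tokens: Iterable[str]) -> list[str]:
    # single letters and digit-bearing tokens never decide interpretability:
    # the "b" in "hepatitis b" should not make or break a term
    return [t for t in tokens if len(t) >= 2 and t.isalpha()]


def term_sense_stats(term: Term, lexicon: WordSenseLexicon) -> TermSenseStats:
    """Token-level lookup: a term's polysemy is the maximum sense count over
    its content tokens; it is interpretable iff any content token has a sense.
    """
    counts = [lexicon.sense_count(t) for t in _content_tokens(term.normalized)]
    return TermSenseStats(term=term, sense_count=max(counts, default=0))


def _parse_table(text: str, source: str) -> dict[str, int]:
    entries: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconResourceError(
                f"{source}:{lineno}: expected two tab-separated columns"
            )
        lemma, count = parts
        try:
            entries[lemma.strip().lower()] = int(count)
        except ValueError as exc:
            raise LexiconResourceError(
                f"{source}:{lineno}: sense count {count!r} is not an integer"
            ) from exc
    return entries


def load_mini_lexicon() -> WordSenseLexicon:
    """Load the bundled deterministic mini-lexicon."""
    text = (
        resources.files("ontosemscore").joinpath("data")
        .joinpath(_MINI_LEXICON_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return WordSenseLexicon(
        entries=_parse_table(text, _MINI_LEXICON_RESOURCE),
        source="bundled-mini",
        version="1",
    )


def load_table_lexicon(path: str | Path) -> WordSenseLexicon:
    """Load a lexicon from a two-column (lemma, sense_count) file."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise LexiconResourceError(f"cannot read lexicon table {path}: {exc}") from exc
    return WordSenseLexicon(entries=_parse_table(text, str(path)), source=str(path))


def load_wordnet_lexicon(dict_dir: str | Path) -> WordSenseLexicon:
    """Adapter for a local WordNet database directory.

    Reads the ``index.{noun,verb,adj,adv}`` files of the standard layout and
    sums synset counts per lemma across parts of speech.  Raises at
    construction (never at lookup) if the layout is missing.
    """
    dict_dir = Path(dict_dir)
    if not dict_dir.is_dir():
        raise LexiconResourceError(f"WordNet directory {dict_dir} does not exist")
    entries: dict[str, int] = {}
    found_any = False
    for name in _WORDNET_INDEX_FILES:
        index_path = dict_dir / name
        if not index_path.exists():
            continue
        found_any = True
        for line in index_path.read_text(encoding="utf-8").splitlines():
            if line.startswith(" ") or not line.strip():
                continue  # license header lines start with two spaces
            fields = line.split()
            if len(fields) < 3:
                continue
            lemma = fields[0].replace("_", " ").lower()
            try:
                synset_cnt = int(fields[2])
            except ValueError:
                continue
            entries[lemma] = entries.get(lemma, 0) + synset_cnt
    if not found_any:
        raise LexiconResourceError(
            f"no WordNet index files found under {dict_dir}"
        )
    return WordSenseLexicon(entries=entries, source="wordnet", version=str(dict_dir))


def load_lexicon(source: str = "bundled-mini", path: str | Path | None = None) -> WordSenseLexicon:
    """Load a lexicon by backend name.

    ``source`` is ``"bundled-mini"``, ``"wordnet"`` (requires ``path`` to a
    WordNet ``dict`` directory) or ``"table"`` (requires ``path``).
    """
    if source in ("bundled-mini", "mini"):
        return load_mini_lexicon()
    if source == "wordnet":
        if path is None:
            raise LexiconResourceError("wordnet backend requires a dict directory path")
        return load_wordnet_lexicon(path)
    if source == "table":
        if path is None:
            raise LexiconResourceError("table backend requires a file path")
        return load_table_lexicon(path)
    raise LexiconResourceError(f"unknown lexicon source {source!r}")
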