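import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from ontosemscore.lexicon import load_mini_lexicon  # noqa: E402

SMALL_TTL = """\
@prefix : <http://example.org/demo#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

<http://example.org/demo> a owl:Ontology .

:Drug a owl:Class ; rdfs:label "Drug" .
:Analgesic a owl:Class ; rdfs:label "Analgesic" .
:AspirinTablet a owl:Class ; rdfs:label "Aspirin Tablet" .
:treats a owl:ObjectProperty .
:a1 a owl:NamedIndividual .
:a2 a owl:NamedIndividual .

:Analgesic rdfs:subClassOf :Drug .
:AspirinTablet rdfs:subClassOf :Analgesic .
:AspirinTablet rdfs:subClassOf :Drug .
:Drug rdfs:subClassOf owl:Thing .
"""

EMPTY_TTL = """\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
<http://example.org/empty> a owl:Ontology .
"""


@pytest.fixture(scope="session")
def mini_lexicon():
    return load_mini_lexicon()


@pytest.fixture()
def small_ttl_path(tmp_path):
    path = tmp_path / "demo.ttl"
    path.write_text(SMALL_TTL, encoding="utf-8")
    return path


@pytest.fixture()
def empty_ttl_path(tmp_path):
    path = tmp_path / "empty.ttl"
    path.write_text(EMPTY_TTL, encoding="utf-8")
    return path
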