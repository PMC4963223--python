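import pytest

from raredx import DiseaseEntry, DiseaseRanker, KnowledgeBase, Symptom
from raredx.synthdata import SyntheticKBSpec, generate_kb


def make_kb(diseases: dict[str, set[str]], extra_symptoms: tuple[str, ...] = ()) -> KnowledgeBase:
    """Build a KnowledgeBase from a {disease_id: symptom ids} mapping."""
    vocab = sorted(set().union(*diseases.values()) | set(extra_symptoms))
    return KnowledgeBase(
        diseases=tuple(
            DiseaseEntry(did, f"disease {did}", frozenset(sym))
            for did, sym in diseases.items()
        ),
        vocabulary=tuple(Symptom(s, f"symptom {s}") for s in vocab),
    )


@pytest.fixture(scope="session")
def toy_kb() -> KnowledgeBase:
    """Three diseases over four symptoms; hand-checkable by enumeration."""
    return make_kb({"D1": {"a", "b"}, "D2": {"b", "c"}, "D3": {"d"}})


@pytest.fixture(scope="session")
def default_kb() -> KnowledgeBase:
    """The default synthetic stand-in knowledge base (2000 x 3000)."""
    return generate_kb(SyntheticKBSpec())


@pytest.fixture(scope="session")
def default_ranker(default_kb) -> DiseaseRanker:
    return DiseaseRanker().fit(default_kb)
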