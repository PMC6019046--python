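import json

import pytest

from semehr_lite import ClinicalNote, default_graph, process_corpus
from semehr_lite.ontology import Concept, OntologyGraph
from semehr_lite.synthcorpus import generate, perfect_recovery_spec


@pytest.fixture(scope="session")
def graph():
    """The bundled mini-UMLS."""
    return default_graph()


@pytest.fixture(scope="session")
def toy_graph():
    """A tiny hand-built hierarchy: hepatitis C under hepatitis C root."""
    return OntologyGraph(
        [
            Concept(cui="C0019196", preferred_name="Hepatitis C",
                    synonyms=frozenset({"hepatitis C", "hep C"})),
            Concept(cui="C2148557", preferred_name="Chronic hepatitis C",
                    synonyms=frozenset({"chronic hepatitis C"}),
                    parents=frozenset({"C0019196"})),
            Concept(cui="C0019699", preferred_name="HIV Pos",
                    synonyms=frozenset({"HIV Pos"})),
        ]
    )


@pytest.fixture(scope="session")
def recovery_corpus(graph):
    """Seed-fixed 100-patient corpus plus its full pipeline output."""
    notes, truth = generate(perfect_recovery_spec(1))
    mentions_by_note, sections_by_note, index = process_corpus(notes, graph)
    return {
        "notes": notes,
        "truth": truth,
        "mentions": mentions_by_note,
        "sections": sections_by_note,
        "index": index,
    }


@pytest.fixture()
def note_factory():
    def make(text, note_id="N1", patient_id="P1", date="2020-01-01",
             note_type="Progress Note"):
        return ClinicalNote(patient_id=patient_id, note_id=note_id, date=date,
                            note_type=note_type, text=text)

    return make


@pytest.fixture()
def write_ontology(tmp_path):
    """Write a concept dictionary + hierarchy to disk for load_ontology."""

    def make(concepts, edges):
        dict_path = tmp_path / "concepts.json"
        hier_path = tmp_path / "hier.tsv"
        dict_path.write_text(json.dumps(concepts))
        hier_path.write_text("".join(f"{c}\t{p}\n" for c, p in edges))
        return dict_path, hier_path

    return make
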