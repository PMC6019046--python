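"""End-to-end convenience: annotate a corpus and build the semantic index."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .annotator import (
    ClinicalNote,
    ConceptMention,
    TriggerLexicon,
    contextualize,
    recognize,
)
from .doc_structure import HeadingDictionary, SectionSpan, assign_sections, detect_sections
from .index_query import SemanticIndex, build_index
from .ontology import OntologyGraph

__all__ = ["process_corpus", "read_notes_jsonl", "write_notes_jsonl"]


def process_corpus(
    notes: Sequence[ClinicalNote],
    graph: OntologyGraph,
    lexicon: TriggerLexicon | None = None,
    hd: HeadingDictionary | None = None,
) -> tuple[dict[str, list[ConceptMention]], dict[str, list[SectionSpan]], SemanticIndex]:
    """Run recognition, contextualization and sectioning over a corpus.

    Returns per-note mentions (contextualized and section-assigned),
    per-note section spans, and the built semantic index.
    """
    if lexicon is None:
        lexicon = TriggerLexicon.default()
    if hd is None:
        hd = HeadingDictionary.default()
    mentions_by_note: dict[str, list[ConceptMention]] = {}
    sections_by_note: dict[str, list[SectionSpan]] = {}
    for note in notes:
        mentions = contextualize(recognize(note, graph), note, lexicon)
        sections = detect_sections(note, hd)
        mentions_by_note[note.note_id] = assign_sections(mentions, sections)
        sections_by_note[note.note_id] = sections
    index = build_index((n, mentions_by_note[n.note_id]) for n in notes)
    return mentions_by_note, sections_by_note, index


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    """One ClinicalNote JSON object per line."""
    notes = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            notes.append(ClinicalNote.from_dict(json.loads(line)))
    return notes


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w") as fh:
        for note in notes:
            fh.write(json.dumps(note.to_dict(), sort_keys=True) + "\n")
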