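"""In-process semantic index and cohort queries.

The index is an inverted map from CUI to contextualized mention references,
plus a patient directory ordering each patient's notes chronologically.  It
is deliberately a plain in-memory structure persisted to a single JSON file:
at desk scale the query contract matters, not the search engine behind it.

Cohort queries take a validated (optionally subsumption-expanded) concept
set and return one summary row per matching patient with the four
contextualized mention counts — positive, history/hypothetical, negated,
other-experiencer — whose sum is always the total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotator import CATEGORIES, ClinicalNote, ConceptMention, categorize
from .ontology import ConceptQuery

__all__ = [
    "MentionRef",
    "SemanticIndex",
    "CohortQuery",
    "CohortSummaryRow",
    "build_index",
    "query_cohort",
    "longitudinal_view",
    "cohort_dataframe",
]


class IndexError_(ValueError):
    """Raised for duplicate notes or unknown patients."""


@dataclass(frozen=True)
class MentionRef:
    """A posting: one contextualized mention occurrence."""

    patient_id: str
    note_id: str
    start: int
    end: int
    category: str
    section: str
    date: str

    def sort_key(self):
        return (self.patient_id, self.date, self.note_id, self.start)


@dataclass(frozen=True)
class NoteMeta:
    note_id: str
    patient_id: str
    date: str
    note_type: str


class SemanticIndex:
    """Inverted index cui -> postings, with a patient note directory."""

    def __init__(self) -> None:
        self.postings: dict[str, list[MentionRef]] = {}
        self.notes: dict[str, NoteMeta] = {}
        self.mentions: dict[str, list[ConceptMention]] = {}

    # -- construction -----------------------------------------------------
    def add_note(self, note: ClinicalNote, mentions: Sequence[ConceptMention]) -> None:
        """Incrementally index one annotated note."""
        if note.note_id in self.notes:
            raise IndexError_(f"duplicate note_id {note.note_id}")
        self.notes[note.note_id] = NoteMeta(
            note.note_id, note.patient_id, note.date, note.note_type
        )
        self.mentions[note.note_id] = list(mentions)
        for m in mentions:
            ref = MentionRef(
                patient_id=note.patient_id,
                note_id=note.note_id,
                start=m.start,
                end=m.end,
                category=categorize(m),
                section=m.section,
                date=note.date,
            )
            self.postings.setdefault(m.cui, []).append(ref)
        for cui in {m.cui for m in mentions}:
            self.postings[cui].sort(key=MentionRef.sort_key)

    # -- lookups ----------------------------------------------------------
    def mentioned_cuis(self) -> set[str]:
        """CUIs with at least one indexed mention (EHR-based exclusion)."""
        return {cui for cui, refs in self.postings.items() if refs}

    def patient_notes(self, patient_id: str) -> list[NoteMeta]:
        """A patient's notes in chronological order (date, then note_id)."""
        notes = [nm for nm in self.notes.values() if nm.patient_id == patient_id]
        if not notes:
            raise IndexError_(f"unknown patient {patient_id}")
        return sorted(notes, key=lambda nm: (nm.date, nm.note_id))

    def patient_ids(self) -> list[str]:
        return sorted({nm.patient_id for nm in self.notes.values()})

    def corpus_stats(self) -> dict[str, int]:
        """Per-CUI total mention counts."""
        return {cui: len(refs) for cui, refs in sorted(self.postings.items())}

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist to a single JSON file (canonical key order)."""
        doc = {
            "notes": [vars(nm) for _, nm in sorted(self.notes.items())],
            "mentions": {
                nid: [m.to_dict() for m in ms]
                for nid, ms in sorted(self.mentions.items())
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SemanticIndex":
        doc = json.loads(Path(path).read_text())
        idx = cls()
        metas = {nm["note_id"]: nm for nm in doc["notes"]}
        for nid in sorted(metas):
            nm = metas[nid]
            note = ClinicalNote(
                patient_id=nm["patient_id"],
                note_id=nm["note_id"],
                date=nm["date"],
                note_type=nm["note_type"],
                text="",
            )
            idx.add_note(
                note,
                [ConceptMention.from_dict(d) for d in doc["mentions"].get(nid, [])],
            )
        return idx


def build_index(
    annotated: Iterable[tuple[ClinicalNote, Sequence[ConceptMention]]]
) -> SemanticIndex:
    """Batch-build an index from (note, mentions) pairs.

    Incremental :meth:`SemanticIndex.add_note` calls produce an identical
    index: rebuilds are deterministic.
    """
    idx = SemanticIndex()
    for note, mentions in annotated:
        idx.add_note(note, mentions)
    return idx


@dataclass
class CohortQuery:
    """A cohort search: concept set plus context/section/date filters."""

    concepts: ConceptQuery
    category_filter: frozenset[str] = frozenset(CATEGORIES)
    section_filter: str | None = None
    date_range: tuple[str, str] | None = None  # inclusive ISO dates

    def __post_init__(self) -> None:
        if not self.category_filter:
            raise ValueError("category_filter must be non-empty")
        unknown = set(self.category_filter) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    def effective_cuis(self) -> list[str]:
        return [c for c in self.concepts.included_cuis if c not in self.concepts.excluded_cuis]

    def passes(self, ref: MentionRef) -> bool:
        if ref.category not in self.category_filter:
            return False
        if self.section_filter is not None and ref.section != self.section_filter:
            return False
        if self.date_range is not None:
            lo, hi = self.date_range
            if not (lo <= ref.date <= hi):
                return False
        return True


@dataclass(frozen=True)
class CohortSummaryRow:
    """Per-patient contextualized mention counts for one query."""

    patient_id: str
    n_total: int
    n_positive: int
    n_hist_hypo: int
    n_negated: int
    n_other: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_positive + self.n_hist_hypo + self.n_negated + self.n_other:
            raise ValueError(f"category counts do not sum to total for {self.patient_id}")


_CAT_FIELD = {
    "positive": "n_positive",
    "historical_hypothetical": "n_hist_hypo",
    "negated": "n_negated",
    "other_experiencer": "n_other",
}


def query_cohort(index: SemanticIndex, q: CohortQuery) -> list[CohortSummaryRow]:
    """One summary row per patient with >=1 mention passing all filters.

    Counts run over the union of the query's included (non-excluded) CUIs;
    rows sort by total count descending, patient id ascending on ties.
    """
    cuis = q.effective_cuis()
    if not cuis:
        raise ValueError("query has no included concepts")
    counts: dict[str, dict[str, int]] = {}
    for cui in cuis:
        for ref in index.postings.get(cui, []):
            if q.passes(ref):
                per = counts.setdefault(
                    ref.patient_id, {f: 0 for f in _CAT_FIELD.values()}
                )
                per[_CAT_FIELD[ref.category]] += 1
    rows = [
        CohortSummaryRow(patient_id=pid, n_total=sum(per.values()), **per)
        for pid, per in counts.items()
    ]
    rows.sort(key=lambda r: (-r.n_total, r.patient_id))
    return rows


def cohort_dataframe(rows: list[CohortSummaryRow]) -> pd.DataFrame:
    """Cohort summary as a DataFrame (CSV columns of the CLI output)."""
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "total": r.n_total,
                "positive": r.n_positive,
                "hist_hypo": r.n_hist_hypo,
                "negated": r.n_negated,
                "other": r.n_other,
            }
            for r in rows
        ],
        columns=["patient_id", "total", "positive", "hist_hypo", "negated", "other"],
    )


def longitudinal_view(
    index: SemanticIndex, patient_id: str, q: CohortQuery | None = None
) -> list[dict]:
    """A patient's documents in chronological order.

    Each entry carries the note id, date and type; when a query is given,
    a ``matched`` flag marks notes with at least one query mention passing
    the query's filters.  Same-day notes order by note_id.
    """
    notes = index.patient_notes(patient_id)
    matched: set[str] = set()
    if q is not None:
        for cui in q.effective_cuis():
            for ref in index.postings.get(cui, []):
                if ref.patient_id == patient_id and q.passes(ref):
                    matched.add(ref.note_id)
    view = []
    for nm in notes:
        entry = {"note_id": nm.note_id, "date": nm.date, "note_type": nm.note_type}
        if q is not None:
            entry["matched"] = nm.note_id in matched
        view.append(entry)
    return view
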