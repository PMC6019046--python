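"""Deterministic concept annotation for clinical notes.

Three stages, all rule-based and reproducible byte-for-byte:

``segment``
    Sentence and token segmentation with character offsets into the raw
    note text (newlines and sentence-final punctuation are boundaries).
``recognize``
    Gazetteer concept recognition: greedy longest match of ontology
    synonyms over token boundaries, case-insensitive, non-overlapping,
    left to right.
``contextualize``
    A ConText/NegEx-style trigger-scope algorithm assigning the three
    context dimensions — negation (affirmed/negated), temporality
    (recent/historical/hypothetical) and experiencer (patient/other).
    Each trigger phrase opens a scope in its direction that runs to the
    sentence boundary, a terminator phrase, or a token cap, and every
    concept mention inside the scope takes the trigger's value for that
    dimension.  The three dimensions are independent; unscoped mentions
    keep the defaults affirmed/recent/patient.

``categorize`` folds the three dimensions into the four cohort-summary
categories (positive, historical/hypothetical, negated, other-experiencer)
with the documented precedence.
"""

from __future__ import annotations

import re
import weakref
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import yaml

from ._normalize import normalize_token
from .ontology import OntologyGraph

__all__ = [
    "ClinicalNote",
    "ConceptMention",
    "TriggerLexicon",
    "TriggerEntry",
    "Sentence",
    "segment",
    "recognize",
    "contextualize",
    "categorize",
    "annotate_note",
    "CATEGORIES",
]

_DATA_DIR = Path(__file__).parent / "data"

Negation = Literal["affirmed", "negated"]
Temporality = Literal["recent", "historical", "hypothetical"]
Experiencer = Literal["patient", "other"]
Category = Literal["positive", "historical_hypothetical", "negated", "other_experiencer"]

CATEGORIES: tuple[Category, ...] = (
    "positive",
    "historical_hypothetical",
    "negated",
    "other_experiencer",
)


@dataclass(frozen=True)
class ClinicalNote:
    """A dated, typed free-text clinical document."""

    patient_id: str
    note_id: str
    date: str  # ISO-8601 YYYY-MM-DD
    note_type: str
    text: str

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "note_id": self.note_id,
            "date": self.date,
            "note_type": self.note_type,
            "text": self.text,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClinicalNote":
        return cls(d["patient_id"], d["note_id"], d["date"], d["note_type"], d["text"])


@dataclass(frozen=True)
class ConceptMention:
    """A located, contextualized concept occurrence.

    Offsets are 0-based half-open character offsets into the raw note text,
    so ``surface == text[start:end]`` always holds.
    """

    note_id: str
    cui: str
    start: int
    end: int
    surface: str
    negation: Negation = "affirmed"
    temporality: Temporality = "recent"
    experiencer: Experiencer = "patient"
    section: str = "unsectioned"
    confidence: float = 1.0

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "cui": self.cui,
            "start": self.start,
            "end": self.end,
            "surface": self.surface,
            "negation": self.negation,
            "temporality": self.temporality,
            "experiencer": self.experiencer,
            "section": self.section,
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConceptMention":
        return cls(**d)


@dataclass(frozen=True)
class Sentence:
    """A sentence span with its token spans (offsets into the note text)."""

    start: int
    end: int
    tokens: tuple[tuple[int, int], ...]


_SENT_BREAK = re.compile(r"[.!?]+(?=\s|$)")
_TOKEN = re.compile(r"\S+")


def segment(text: str) -> list[Sentence]:
    """Split *text* into sentences and tokens, preserving offsets.

    Newlines always end a sentence (so headed-list lines stay separate);
    within a line, runs of ``.!?`` followed by whitespace or end of line
    close a sentence and belong to it.  Empty/whitespace-only chunks
    produce no sentence.
    """
    sentences: list[Sentence] = []
    line_start = 0
    for line in text.split("\n"):
        line_end = line_start + len(line)
        chunk_start = line_start
        breaks = [m.end() for m in _SENT_BREAK.finditer(line)]
        for b in breaks + [len(line)]:
            chunk_end = line_start + b
            if chunk_end > chunk_start:
                raw = text[chunk_start:chunk_end]
                tokens = tuple(
                    (chunk_start + m.start(), chunk_start + m.end())
                    for m in _TOKEN.finditer(raw)
                )
                if tokens:
                    sentences.append(
                        Sentence(start=tokens[0][0], end=tokens[-1][1], tokens=tokens)
                    )
            chunk_start = chunk_end
        line_start = line_end + 1
    return sentences


class _PhraseIndex:
    """Token-level phrase lookup: tuple of normalized tokens -> payload."""

    def __init__(self) -> None:
        self._table: dict[tuple[str, ...], set] = {}
        self.max_len = 0

    def add(self, phrase: str, payload) -> None:
        key = tuple(
            t for t in (normalize_token(tok) for tok in phrase.split()) if t
        )
        if not key:
            return
        self._table.setdefault(key, set()).add(payload)
        self.max_len = max(self.max_len, len(key))

    def get(self, key: tuple[str, ...]) -> set | None:
        return self._table.get(key)


_graph_index_cache: "weakref.WeakKeyDictionary[OntologyGraph, _PhraseIndex]" = (
    weakref.WeakKeyDictionary()
)


def _phrase_index_for(graph: OntologyGraph) -> _PhraseIndex:
    cached = _graph_index_cache.get(graph)
    if cached is not None:
        return cached
    idx = _PhraseIndex()
    for cui in sorted(graph.concepts):
        for name in sorted(graph.concepts[cui].all_names()):
            idx.add(name, cui)
    _graph_index_cache[graph] = idx
    return idx


def _scan_phrases(
    norm_tokens: Sequence[str], index: _PhraseIndex
) -> list[tuple[int, int, set]]:
    """Greedy longest-match scan; returns (tok_start, tok_end_excl, payloads)."""
    out = []
    i, n = 0, len(norm_tokens)
    while i < n:
        if not norm_tokens[i]:
            i += 1
            continue
        hit = None
        for length in range(min(index.max_len, n - i), 0, -1):
            window = tuple(norm_tokens[i : i + length])
            if "" in window:
                continue
            payloads = index.get(window)
            if payloads is not None:
                hit = (i, i + length, payloads)
                break
        if hit is not None:
            out.append(hit)
            i = hit[1]
        else:
            i += 1
    return out


def _resolve_cui(graph: OntologyGraph, cuis: set, surface: str) -> str:
    """Ambiguity tie-break: prefer the concept whose preferred name is the
    surface form (after normalization); else the lexicographically lowest
    CUI.  Stable and documented in place of a learned disambiguator."""
    if len(cuis) == 1:
        return next(iter(cuis))
    norm_surface = " ".join(
        t for t in (normalize_token(tok) for tok in surface.split()) if t
    )
    preferred = sorted(
        c
        for c in cuis
        if " ".join(
            t
            for t in (
                normalize_token(tok)
                for tok in graph.concepts[c].preferred_name.split()
            )
            if t
        )
        == norm_surface
    )
    if preferred:
        return preferred[0]
    return min(cuis)


_CORE = re.compile(r"\w(?:.*\w)?", re.DOTALL)


def _core_span(token: str) -> tuple[int, int]:
    """Offsets of the token minus its edge punctuation ("C?." -> "C")."""
    m = _CORE.search(token)
    return (m.start(), m.end()) if m else (0, len(token))


def recognize(note: ClinicalNote, graph: OntologyGraph) -> list[ConceptMention]:
    """Gazetteer recognition: longest-match dictionary phrases over tokens.

    Mention spans are trimmed to the token cores, so sentence punctuation
    around a matched phrase is not part of the surface.  Returns mentions
    with context fields at their defaults (affirmed/recent/patient) and
    confidence 1.0.
    """
    index = _phrase_index_for(graph)
    mentions: list[ConceptMention] = []
    for sent in segment(note.text):
        norm = [normalize_token(note.text[s:e]) for s, e in sent.tokens]
        for ti, tj, cuis in _scan_phrases(norm, index):
            s0, e0 = sent.tokens[ti]
            s1, e1 = sent.tokens[tj - 1]
            start = s0 + _core_span(note.text[s0:e0])[0]
            end = s1 + _core_span(note.text[s1:e1])[1]
            surface = note.text[start:end]
            mentions.append(
                ConceptMention(
                    note_id=note.note_id,
                    cui=_resolve_cui(graph, cuis, surface),
                    start=start,
                    end=end,
                    surface=surface,
                )
            )
    return mentions


Direction = Literal["forward", "backward", "bidirectional"]


@dataclass(frozen=True)
class TriggerEntry:
    """One context trigger: a phrase that opens a scope for one dimension."""

    phrase: str
    dimension: Literal["negation", "temporality", "experiencer"]
    value: str
    direction: Direction = "forward"
    scope_limit: int | None = 8  # tokens; None = sentence-bounded only


@dataclass
class TriggerLexicon:
    """Trigger phrases plus scope terminators for the context algorithm."""

    entries: list[TriggerEntry] = field(default_factory=list)
    terminators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e.phrase or e.phrase != e.phrase.lower():
                raise ValueError(f"trigger phrase must be non-empty lower-case: {e.phrase!r}")
            if e.scope_limit is not None and e.scope_limit < 1:
                raise ValueError(f"scope_limit must be >= 1: {e.phrase!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriggerLexicon":
        """Load a lexicon from YAML.

        Schema::

            scope_limit: 8          # default token cap
            terminators: [but, however]
            triggers:
              negation:
                negated: {forward: [...], backward: [...]}
              temporality:
                historical: {forward: [...]}
                hypothetical: {forward: [...]}
              experiencer:
                other: {forward: [...], bidirectional: [...]}
        """
        raw = yaml.safe_load(Path(path).read_text())
        default_scope = raw.get("scope_limit", 8)
        entries = []
        for dimension, values in raw.get("triggers", {}).items():
            for value, by_direction in values.items():
                for direction, phrases in by_direction.items():
                    for phrase in phrases:
                        entries.append(
                            TriggerEntry(
                                phrase=phrase,
                                dimension=dimension,
                                value=value,
                                direction=direction,
                                scope_limit=default_scope,
                            )
                        )
        return cls(entries=entries, terminators=list(raw.get("terminators", [])))

    @classmethod
    def default(cls) -> "TriggerLexicon":
        """The packaged default lexicon (loaded once per process)."""
        global _default_lexicon
        if _default_lexicon is None:
            _default_lexicon = cls.from_yaml(_DATA_DIR / "triggers.yaml")
        return _default_lexicon

    def all_phrases(self) -> set[str]:
        return {e.phrase for e in self.entries} | set(self.terminators)


_default_lexicon: "TriggerLexicon | None" = None
_lexicon_index_cache: dict[int, tuple["TriggerLexicon", tuple]] = {}


def _trigger_indexes_cached(lexicon: TriggerLexicon) -> tuple[_PhraseIndex, _PhraseIndex]:
    hit = _lexicon_index_cache.get(id(lexicon))
    if hit is not None and hit[0] is lexicon:
        return hit[1]
    indexes = _trigger_indexes(lexicon)
    _lexicon_index_cache[id(lexicon)] = (lexicon, indexes)
    return indexes


def _trigger_indexes(lexicon: TriggerLexicon) -> tuple[_PhraseIndex, _PhraseIndex]:
    trig = _PhraseIndex()
    for e in lexicon.entries:
        trig.add(e.phrase, e)
    term = _PhraseIndex()
    for t in lexicon.terminators:
        term.add(t, "terminator")
    return trig, term


def contextualize(
    mentions: list[ConceptMention],
    note: ClinicalNote,
    lexicon: TriggerLexicon | None = None,
) -> list[ConceptMention]:
    """Assign negation/temporality/experiencer by trigger scopes.

    Within each sentence, triggers are located by the same longest-match
    scan as concept recognition.  A forward trigger's scope is the tokens
    after it up to the sentence end, the first terminator, or its token
    cap; a backward trigger mirrors this to the left; bidirectional covers
    both sides.  Triggers are applied in sentence order, so when two
    scopes of the same dimension cover a mention the later (nearer) trigger
    wins.  Dimensions are independent.
    """
    if lexicon is None:
        lexicon = TriggerLexicon.default()
    trig_idx, term_idx = _trigger_indexes_cached(lexicon)
    out = list(mentions)
    sentences = segment(note.text)
    # mention index by start offset for in-place context updates
    by_start = {m.start: i for i, m in enumerate(out)}
    for sent in sentences:
        norm = [normalize_token(note.text[s:e]) for s, e in sent.tokens]
        n = len(norm)
        hits = _scan_phrases(norm, trig_idx)
        if not hits:
            continue
        term_positions = sorted(t0 for t0, _, _ in _scan_phrases(norm, term_idx))
        # token index of each mention starting in this sentence
        mention_tokens: list[tuple[int, int]] = []  # (token_idx, mention_idx)
        for ti, (s, _e) in enumerate(sent.tokens):
            if s in by_start:
                mention_tokens.append((ti, by_start[s]))
        for t0, t1, entries in hits:
            for entry in sorted(entries, key=lambda e: (e.dimension, e.value, e.direction)):
                cap = entry.scope_limit if entry.scope_limit is not None else n
                ranges: list[tuple[int, int]] = []
                if entry.direction in ("forward", "bidirectional"):
                    lo, hi = t1, min(n, t1 + cap)
                    for tp in term_positions:
                        if lo <= tp < hi:
                            hi = tp
                            break
                    ranges.append((lo, hi))
                if entry.direction in ("backward", "bidirectional"):
                    lo, hi = max(0, t0 - cap), t0
                    for tp in reversed(term_positions):
                        if lo <= tp < hi:
                            lo = tp + 1
                            break
                    ranges.append((lo, hi))
                for lo, hi in ranges:
                    for ti, mi in mention_tokens:
                        if lo <= ti < hi:
                            out[mi] = replace(
                                out[mi], **{entry.dimension: entry.value}
                            )
    return out


def categorize(m: ConceptMention) -> Category:
    """Fold the three context dimensions into one cohort category.

    Precedence: other_experiencer > negated > historical_hypothetical >
    positive; a mention is positive iff affirmed, recent and about the
    patient.
    """
    if m.experiencer == "other":
        return "other_experiencer"
    if m.negation == "negated":
        return "negated"
    if m.temporality in ("historical", "hypothetical"):
        return "historical_hypothetical"
    return "positive"


def annotate_note(
    note: ClinicalNote,
    graph: OntologyGraph,
    lexicon: TriggerLexicon | None = None,
) -> list[ConceptMention]:
    """recognize + contextualize in one call."""
    return contextualize(recognize(note, graph), note, lexicon)
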