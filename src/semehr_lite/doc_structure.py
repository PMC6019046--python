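"""Document-structure analysis: document types and headed sections.

Clinical notes — discharge summaries in particular — are organised under
conventional headings ("PAST MEDICAL HISTORY:", "Family History:", ...).
This module detects those headed blocks, maps each heading onto a canonical
section set (the 23 FHIR CCDA discharge-summary sections plus 8 configurable
extensions, 31 labels in total), and attaches a section label to every
concept mention so that downstream queries can be section-constrained
(e.g. "family history of hepatitis C").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import yaml

from ._normalize import normalize_heading
from .annotator import ClinicalNote, ConceptMention

__all__ = [
    "SectionSpan",
    "HeadingDictionary",
    "classify_doc_type",
    "detect_sections",
    "assign_sections",
]

_DATA_DIR = Path(__file__).parent / "data"

# A heading is a whole line that is either a short title ending in a colon,
# or an all-caps short title (with or without colon handled by first branch).
_HEADING_LINE = re.compile(
    r"^\s*[A-Za-z][A-Za-z /&-]{1,60}:\s*$|^\s*[A-Z][A-Z /&-]{2,60}\s*$"
)

UNSECTIONED = "unsectioned"
OTHER = "Other"


@dataclass(frozen=True)
class SectionSpan:
    """One headed block: [start, end) runs from the heading line to the
    next heading or end of text."""

    heading_raw: str
    heading_canonical: str
    start: int
    end: int


@dataclass
class HeadingDictionary:
    """Canonical section labels plus normalized heading aliases."""

    canonical_labels: list[str] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # every canonical label resolves to itself
        for label in self.canonical_labels:
            self.aliases.setdefault(normalize_heading(label), label)
        bad = {a: c for a, c in self.aliases.items() if c not in self.canonical_labels}
        if bad:
            raise ValueError(f"aliases map to unknown canonical labels: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HeadingDictionary":
        raw = yaml.safe_load(Path(path).read_text())
        labels: list[str] = []
        aliases: dict[str, str] = {}
        for group in ("fhir_labels", "extension_labels"):
            for label, alias_list in raw.get(group, {}).items():
                labels.append(label)
                for alias in alias_list or []:
                    aliases[normalize_heading(alias)] = label
        return cls(canonical_labels=labels, aliases=aliases)

    @classmethod
    def default(cls) -> "HeadingDictionary":
        global _default_hd
        if _default_hd is None:
            _default_hd = cls.from_yaml(_DATA_DIR / "headings.yaml")
        return _default_hd

    def canonical(self, heading_raw: str) -> str:
        """Canonical label for a raw heading, or "Other" when unmapped."""
        return self.aliases.get(normalize_heading(heading_raw), OTHER)


_default_hd: "HeadingDictionary | None" = None


@lru_cache(maxsize=1)
def _load_doc_type_rules() -> list[tuple[str, str]]:
    raw = yaml.safe_load((_DATA_DIR / "doc_types.yaml").read_text())
    return [(r["keyword"].lower(), r["type"]) for r in raw["keyword_rules"]]


def classify_doc_type(note: ClinicalNote, rules: list[tuple[str, str]] | None = None) -> str:
    """Derive the document type.

    The note's own ``note_type`` metadata wins when present; otherwise
    keyword rules are applied to the first 500 characters; otherwise
    "Unknown".
    """
    if note.note_type:
        return note.note_type
    head = note.text[:500].lower()
    for keyword, doc_type in rules if rules is not None else _load_doc_type_rules():
        if keyword in head:
            return doc_type
    return "Unknown"


def detect_sections(
    note: ClinicalNote, hd: HeadingDictionary | None = None
) -> list[SectionSpan]:
    """Detect headed blocks and canonicalize their headings.

    Each heading line opens a span that runs to the next heading line or
    the end of the text; spans are ordered and non-overlapping, so every
    character at or after the first heading belongs to exactly one span.
    Headings with no alias map to "Other" rather than being dropped.
    """
    if hd is None:
        hd = HeadingDictionary.default()
    heads: list[tuple[int, str]] = []  # (line start offset, heading text)
    offset = 0
    for line in note.text.split("\n"):
        if _HEADING_LINE.match(line):
            heads.append((offset, line.strip()))
        offset += len(line) + 1
    spans: list[SectionSpan] = []
    for i, (start, raw) in enumerate(heads):
        end = heads[i + 1][0] if i + 1 < len(heads) else len(note.text)
        spans.append(
            SectionSpan(
                heading_raw=raw,
                heading_canonical=hd.canonical(raw),
                start=start,
                end=end,
            )
        )
    return spans


def assign_sections(
    mentions: list[ConceptMention], sections: list[SectionSpan]
) -> list[ConceptMention]:
    """Label each mention with the canonical section containing its start.

    Mentions before the first heading (or in an unheaded note) get
    "unsectioned".  Returns new mention objects; input order is preserved.
    """
    out: list[ConceptMention] = []
    for m in mentions:
        label = UNSECTIONED
        for span in sections:
            if span.start <= m.start < span.end:
                label = span.heading_canonical
                break
        out.append(ConceptMention(**{**m.to_dict(), "section": label}))
    return out
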