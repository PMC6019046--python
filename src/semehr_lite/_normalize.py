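"""Shared string normalization for term, synonym and heading lookup.

All dictionary-style lookups in the package (ontology synonyms, trigger
phrases, section headings, measurement aliases) go through the same rule:
Unicode NFKC, case-fold, collapse internal whitespace, strip leading and
trailing punctuation.  Exact-match-after-normalization keeps every lookup
auditable; there is deliberately no fuzzy matching.
"""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")
# punctuation stripped only at the edges so internal hyphens/slashes survive
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$")


def normalize_term(term: str) -> str:
    """Normalize a free-text term for dictionary lookup."""
    s = unicodedata.normalize("NFKC", term).casefold()
    s = _WS.sub(" ", s).strip()
    s = _EDGE_PUNCT.sub("", s)
    return s


def normalize_token(token: str) -> str:
    """Normalize a single token (edge punctuation dropped, case-folded)."""
    s = unicodedata.normalize("NFKC", token).casefold()
    return _EDGE_PUNCT.sub("", s)


def normalize_heading(heading: str) -> str:
    """Normalize a section heading before alias lookup.

    Case-fold, strip a trailing colon, collapse whitespace.
    """
    s = unicodedata.normalize("NFKC", heading).casefold().strip()
    if s.endswith(":"):
        s = s[:-1]
    return _WS.sub(" ", s).strip()
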