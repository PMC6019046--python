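"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way, without
reusing the package's data structures, so oracle agreement is meaningful.
"""

from __future__ import annotations

import re
import unicodedata

# --- subsumption closure ----------------------------------------------------


def bfs_closure(edges: list[tuple[str, str]], seeds: set[str]) -> set[str]:
    """Seeds plus all nodes reachable by child-edges from them.

    *edges* are (child, parent) pairs; reachability follows parent->child.
    """
    children: dict[str, list[str]] = {}
    for child, parent in edges:
        children.setdefault(parent, []).append(child)
    out = set(seeds)
    frontier = list(seeds)
    while frontier:
        node = frontier.pop()
        for ch in children.get(node, []):
            if ch not in out:
                out.add(ch)
                frontier.append(ch)
    return out


# --- trigger scope evaluation ------------------------------------------------


def _norm(tok: str) -> str:
    s = unicodedata.normalize("NFKC", tok).casefold()
    return re.sub(r"^[^\w]+|[^\w]+$", "", s)


def _sentences(text: str) -> list[list[tuple[int, int]]]:
    """Token spans grouped into sentences (newline or .!? boundaries)."""
    sentences = []
    line_start = 0
    for line in text.split("\n"):
        chunk_start = line_start
        bounds = [m.end() for m in re.finditer(r"[.!?]+(?=\s|$)", line)]
        for b in bounds + [len(line)]:
            chunk_end = line_start + b
            toks = [
                (chunk_start + m.start(), chunk_start + m.end())
                for m in re.finditer(r"\S+", text[chunk_start:chunk_end])
            ]
            if toks:
                sentences.append(toks)
            chunk_start = chunk_end
        line_start += len(line) + 1
    return sentences


def _find_phrases(norm_tokens, phrases):
    """Greedy left-to-right longest-match occurrences of phrase token
    tuples; returns (tok_start, tok_end_excl, phrase_key)."""
    out = []
    i = 0
    while i < len(norm_tokens):
        best = None
        for key in phrases:
            L = len(key)
            if i + L <= len(norm_tokens) and tuple(norm_tokens[i : i + L]) == key:
                if best is None or L > len(best):
                    best = key
        if best is not None:
            out.append((i, i + len(best), best))
            i += len(best)
        else:
            i += 1
    return out


def naive_context(text, mention_spans, lexicon):
    """Brute-force context assignment: for every sentence, every trigger and
    every mention, test scope coverage directly.

    *mention_spans* is a list of (start, end) character spans.  Returns one
    {negation, temporality, experiencer} dict per span, in order.
    """
    entries = {}
    for e in lexicon.entries:
        key = tuple(_norm(t) for t in e.phrase.split())
        entries.setdefault(key, []).append(e)
    term_keys = [tuple(_norm(t) for t in p.split()) for p in lexicon.terminators]
    trigger_keys = list(entries)

    results = [
        {"negation": "affirmed", "temporality": "recent", "experiencer": "patient"}
        for _ in mention_spans
    ]
    for toks in _sentences(text):
        norm = [_norm(text[a:b]) for a, b in toks]
        n = len(norm)
        occurrences = _find_phrases(norm, trigger_keys)
        terminators = [a for a, _b, _k in _find_phrases(norm, term_keys)]
        mention_tok = {}
        for mi, (s, _e) in enumerate(mention_spans):
            for ti, (a, b) in enumerate(toks):
                if a <= s < b:
                    mention_tok[mi] = ti
        for t0, t1, key in occurrences:
            for entry in sorted(
                entries[key], key=lambda e: (e.dimension, e.value, e.direction)
            ):
                cap = entry.scope_limit if entry.scope_limit is not None else n
                covered = set()
                if entry.direction in ("forward", "bidirectional"):
                    hi = min(n, t1 + cap)
                    for tp in sorted(terminators):
                        if t1 <= tp < hi:
                            hi = tp
                            break
                    covered |= set(range(t1, hi))
                if entry.direction in ("backward", "bidirectional"):
                    lo = max(0, t0 - cap)
                    for tp in sorted(terminators, reverse=True):
                        if lo <= tp < t0:
                            lo = tp + 1
                            break
                    covered |= set(range(lo, t0))
                for mi, ti in mention_tok.items():
                    if ti in covered:
                        results[mi][entry.dimension] = entry.value
    return results


# --- cohort recount ----------------------------------------------------------


def linear_scan_cohort(mentions, note_meta, cuis, categories, section, date_range):
    """Recount a cohort query by scanning every mention directly.

    *mentions* is a list of (note_id, cui, category, section); *note_meta*
    maps note_id -> (patient_id, date).  Returns {patient_id: (total,
    positive, hist_hypo, negated, other)}.
    """
    order = ["positive", "historical_hypothetical", "negated", "other_experiencer"]
    counts = {}
    for note_id, cui, category, msection in mentions:
        if cui not in cuis or category not in categories:
            continue
        if section is not None and msection != section:
            continue
        pid, date = note_meta[note_id]
        if date_range is not None and not (date_range[0] <= date <= date_range[1]):
            continue
        per = counts.setdefault(pid, [0, 0, 0, 0])
        per[order.index(category)] += 1
    return {
        pid: (sum(per), per[0], per[1], per[2], per[3]) for pid, per in counts.items()
    }
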