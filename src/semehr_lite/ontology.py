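"""Mini-UMLS concept dictionary with is-a subsumption reasoning.

A concept dictionary (JSON array) plus an is-a hierarchy (two-column TSV,
``child<TAB>parent``) are loaded into an :class:`OntologyGraph`.  The graph
supports the three query-translation steps used when turning a clinician's
search terms into a validated concept set:

1. term matching — exact lookup of a normalized term in the synonym index;
2. subsumption expansion — transitive is-a descendant closure, so a query
   for "liver damage" also retrieves "hepatocellular damage";
3. EHR-based exclusion — dropping candidate concepts that never occur in
   the indexed corpus.

The hierarchy is a poly-hierarchy (DAG, multiple parents allowed), as in
UMLS/SNOMED CT.  Only is-a reasoning is implemented: subsumption is the one
form of reasoning the query-expansion contract requires; relations such as
"may treat" are not followed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

from ._normalize import normalize_term

__all__ = [
    "Concept",
    "OntologyGraph",
    "ConceptQuery",
    "OntologyError",
    "load_ontology",
    "match_term",
    "expand_concepts",
    "ehr_exclude",
    "apply_validation",
]


class OntologyError(ValueError):
    """Raised for malformed dictionaries/hierarchies or unknown CUIs."""


@dataclass(frozen=True)
class Concept:
    """One node of the mini-UMLS: a concept with its synonyms and codes.

    Parameters
    ----------
    cui
        Concept Unique Identifier, ``C`` followed by digits (e.g. C0019699).
    preferred_name
        Canonical display name; always part of the matchable synonym set.
    synonyms
        Surface forms that should link to this concept.
    semantic_type
        UMLS-style semantic type, e.g. ``"Disease or Syndrome"``.
    parents
        CUIs of direct is-a parents (poly-hierarchy allowed).
    source_codes
        Source-vocabulary codes, vocabulary name -> code string.
    """

    cui: str
    preferred_name: str
    synonyms: frozenset[str] = frozenset()
    semantic_type: str = ""
    parents: frozenset[str] = frozenset()
    source_codes: Mapping[str, str] = field(default_factory=dict)

    def all_names(self) -> frozenset[str]:
        """Synonyms plus the preferred name (the matchable surface forms)."""
        return self.synonyms | {self.preferred_name}


class OntologyGraph:
    """Concept dictionary plus acyclic is-a hierarchy with a synonym index.

    The is-a edges are held in a :class:`networkx.DiGraph` pointing from
    parent to child, so descendant closure is a reachability query.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        self.name_index: dict[str, set[str]] = {}
        self._dag = nx.DiGraph()
        for c in concepts:
            if c.cui in self.concepts:
                raise OntologyError(f"duplicate cui {c.cui}")
            self.concepts[c.cui] = c
            self._dag.add_node(c.cui)
        for c in self.concepts.values():
            for name in c.all_names():
                key = normalize_term(name)
                if key:
                    self.name_index.setdefault(key, set()).add(c.cui)
            for parent in c.parents:
                if parent not in self.concepts:
                    raise OntologyError(
                        f"dangling parent cui {parent} (child {c.cui})"
                    )
                self._dag.add_edge(parent, c.cui)
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise OntologyError(f"is-a hierarchy contains a cycle: {cycle}")

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def descendants(self, cui: str) -> set[str]:
        """Transitive is-a descendants of *cui* (excluding *cui* itself)."""
        if cui not in self.concepts:
            raise OntologyError(f"unknown cui {cui}")
        return set(nx.descendants(self._dag, cui))

    def roots(self) -> set[str]:
        """CUIs with no parents."""
        return {c for c, d in self._dag.in_degree() if d == 0}


ValidationState = Literal["auto", "approved", "rejected"]


@dataclass
class ConceptQuery:
    """A validated concept set: the unit a cohort query searches for.

    ``included_cuis`` keeps insertion order (seed concepts first, then
    expansion); every included or excluded cui carries a validation state.
    """

    included_cuis: list[str] = field(default_factory=list)
    excluded_cuis: set[str] = field(default_factory=set)
    origin_terms: list[str] = field(default_factory=list)
    validation_state: dict[str, ValidationState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.included_cuis) & self.excluded_cuis
        if overlap:
            raise OntologyError(
                f"cuis both included and excluded: {sorted(overlap)}"
            )
        for cui in list(self.included_cuis) + sorted(self.excluded_cuis):
            self.validation_state.setdefault(cui, "auto")

    @classmethod
    def from_terms(
        cls, graph: OntologyGraph, terms: Iterable[str], expand: bool = True
    ) -> "ConceptQuery":
        """Build a query by matching terms and (optionally) expanding them."""
        terms = list(terms)
        seeds: list[str] = []
        for t in terms:
            for cui in sorted(match_term(graph, t)):
                if cui not in seeds:
                    seeds.append(cui)
        included = list(seeds)
        if expand:
            for cui in sorted(expand_concepts(graph, set(seeds))):
                if cui not in included:
                    included.append(cui)
        return cls(included_cuis=included, origin_terms=terms)


def load_ontology(dictionary_path: str | Path, hierarchy_path: str | Path | None) -> OntologyGraph:
    """Load a concept dictionary (JSON) and an is-a hierarchy (TSV).

    The dictionary is a JSON array of objects with keys ``cui``,
    ``preferred_name``, ``synonyms`` (list), ``semantic_type`` and
    ``source_codes`` (object).  The hierarchy file has one
    ``child<TAB>parent`` edge per line; blank lines and ``#`` comments are
    ignored.  Loading is deterministic; cycles and dangling parent CUIs are
    rejected with the offending edge/cui named.
    """
    raw = json.loads(Path(dictionary_path).read_text())
    parents: dict[str, set[str]] = {}
    if hierarchy_path is not None:
        for lineno, line in enumerate(
            Path(hierarchy_path).read_text().splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(
                    f"{hierarchy_path}:{lineno}: expected child<TAB>parent"
                )
            child, parent = parts[0].strip(), parts[1].strip()
            parents.setdefault(child, set()).add(parent)
    concepts = []
    for obj in raw:
        cui = obj["cui"]
        concepts.append(
            Concept(
                cui=cui,
                preferred_name=obj["preferred_name"],
                synonyms=frozenset(obj.get("synonyms", [])),
                semantic_type=obj.get("semantic_type", ""),
                parents=frozenset(parents.get(cui, set())),
                source_codes=dict(obj.get("source_codes", {})),
            )
        )
    unknown_children = sorted(set(parents) - {c.cui for c in concepts})
    if unknown_children:
        raise OntologyError(
            f"hierarchy references cuis absent from dictionary: {unknown_children}"
        )
    return OntologyGraph(concepts)


def match_term(graph: OntologyGraph, term: str) -> set[str]:
    """All CUIs whose synonym set contains the normalized *term*.

    Matching is exact after normalization (case-fold, collapse whitespace,
    strip edge punctuation); the empty set is a valid no-match result.
    """
    if not term:
        raise OntologyError("empty search term")
    return set(graph.name_index.get(normalize_term(term), set()))


def expand_concepts(graph: OntologyGraph, seeds: set[str]) -> set[str]:
    """Seeds plus all transitive is-a descendants of each seed.

    Monotone and idempotent; a leaf concept expands to itself.
    """
    unknown = sorted(set(seeds) - set(graph.concepts))
    if unknown:
        raise OntologyError(f"unknown cuis in seeds: {unknown}")
    out = set(seeds)
    for cui in seeds:
        out |= graph.descendants(cui)
    return out


def ehr_exclude(candidates: set[str], index) -> set[str]:
    """Restrict *candidates* to concepts with at least one indexed mention.

    *index* is a :class:`semehr_lite.index_query.SemanticIndex` (anything
    exposing ``mentioned_cuis()``).
    """
    return set(candidates) & index.mentioned_cuis()


def apply_validation(
    query: ConceptQuery, decisions: Iterable[tuple[str, str]]
) -> ConceptQuery:
    """Apply manual approve/reject decisions to a query.

    Rejected CUIs move to the excluded set; approved ones are flagged.
    Returns a new :class:`ConceptQuery`; the input is not mutated.
    """
    included = list(query.included_cuis)
    excluded = set(query.excluded_cuis)
    states = dict(query.validation_state)
    known = set(included) | excluded
    for cui, decision in decisions:
        if cui not in known:
            raise OntologyError(f"validation decision on unknown cui {cui}")
        if decision == "approve":
            states[cui] = "approved"
        elif decision == "reject":
            states[cui] = "rejected"
            if cui in included:
                included.remove(cui)
            excluded.add(cui)
        else:
            raise OntologyError(f"unknown decision {decision!r} for {cui}")
    return ConceptQuery(
        included_cuis=included,
        excluded_cuis=excluded,
        origin_terms=list(query.origin_terms),
        validation_state=states,
    )
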