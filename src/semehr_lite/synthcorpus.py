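"""Synthetic clinical-note corpora with exact ground truth.

Real clinical corpora behind the pipeline's design are access-restricted,
so every stage here is exercised on generated data instead.  The generator
composes notes exclusively from

* concept surface forms drawn from the loaded ontology,
* trigger phrases drawn from the loaded context lexicon,
* heading lines drawn from the canonical heading dictionary,
* measurement lines drawn from the measurement rule table, and
* a closed neutral filler vocabulary verified disjoint from all of the
  above,

so the rule-based annotator can in principle recover the injected
annotations perfectly, and the emitted :class:`GroundTruth` is exact by
construction rather than by re-annotation.

Per patient, the number of *positive* mentions of each study disease is
drawn from a class-conditional Poisson (cases vs controls), which makes the
generated cohorts a controlled test bed for the mention-count classifier;
per-mention context combinations, section placement, and free-text lab
values (optionally corrupted relative to the structured lab table) cover
the remaining layers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotator import ClinicalNote, ConceptMention, TriggerLexicon, categorize
from .doc_structure import HeadingDictionary, SectionSpan
from .ontology import OntologyGraph, load_ontology
from .profile import MeasurementRuleTable

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "generate",
    "score_against_truth",
    "default_graph",
    "perfect_recovery_spec",
    "hepatitis_c_study_spec",
    "hiv_study_spec",
    "FILLER_VOCAB",
]

_DATA_DIR = Path(__file__).parent / "data"

# Neutral connective vocabulary; generate() verifies that no dictionary
# synonym, trigger phrase, terminator or measurement alias can be assembled
# from these tokens alone.
FILLER_VOCAB: tuple[str, ...] = (
    "patient", "attended", "clinic", "today", "morning", "reviewed",
    "remains", "stable", "overall", "comfortable", "settled", "routine",
    "observations", "recorded", "unchanged", "ambulating", "independently",
    "tolerating", "meals", "discussed", "ongoing", "recovery", "improving",
    "gradually", "appointment", "arranged", "ward", "team", "monitoring",
    "continues", "satisfactory",
)

DEFAULT_CONTEXT_MIX: dict[str, float] = {
    "affirmed|recent|patient": 0.55,
    "negated|recent|patient": 0.12,
    "affirmed|historical|patient": 0.10,
    "affirmed|recent|other": 0.08,
    "affirmed|hypothetical|patient": 0.06,
    "negated|historical|patient": 0.03,
    "negated|recent|other": 0.02,
    "affirmed|historical|other": 0.02,
    "negated|hypothetical|patient": 0.01,
    "negated|hypothetical|other": 0.004,
    "affirmed|hypothetical|other": 0.003,
    "negated|historical|other": 0.003,
}

# trigger phrases the generator composes sentences from (all forward);
# checked against the loaded lexicon at generate() time
_GEN_TRIGGERS = {
    "negated": ("no evidence of", "denies", "negative for", "without"),
    "historical": ("history of", "previous"),
    "hypothetical": ("risk of", "possible"),
    "other": ("father", "mother", "brother", "sister"),
}

_DS_LAYOUT = (
    "History of Present Illness",
    "History of Past Illness",
    "Family History",
    "Social History",
    "Admission Medications",
    "Hospital Discharge Physical",
    "Hospital Discharge Instructions",
)


class SynthSpecError(ValueError):
    """Raised when a spec references unknown concepts/headings/triggers."""


@dataclass
class SynthSpec:
    """Generator parameters: the conditions a synthetic study runs under.

    ``disease_prevalence`` maps each study disease (a root CUI) to the
    probability a patient is a case for it; positive-mention counts per
    patient come from ``Poisson(lambda_case)`` for cases and
    ``Poisson(lambda_control)`` for controls, spread over the root's
    subsumption closure (or an explicit ``disease_groups`` entry).
    """

    seed: int
    n_patients: int = 100
    notes_per_patient: tuple[int, int] = (4, 6)
    disease_prevalence: dict[str, float] = field(
        default_factory=lambda: {"C0019196": 0.165}
    )
    disease_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    lambda_case: float = 3.0
    lambda_control: float = 0.001
    nonpositive_disease_rate: float = 0.8
    background_rate: float = 1.5
    context_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_MIX)
    )
    section_layout: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {"Discharge Summary": _DS_LAYOUT}
    )
    note_type_weights: dict[str, float] = field(
        default_factory=lambda: {"Progress Note": 0.7, "Radiology": 0.2, "GP Letter": 0.1}
    )
    labs_per_summary: tuple[int, int] = (3, 7)
    extra_lab_values: tuple[int, int] = (0, 2)
    corruption_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SynthSpecError("seed is mandatory")
        for name, p in [("corruption_rate", self.corruption_rate)] + [
            (f"prevalence[{c}]", p) for c, p in self.disease_prevalence.items()
        ]:
            if not 0.0 <= p <= 1.0:
                raise SynthSpecError(f"{name} must be in [0,1], got {p}")
        if self.lambda_case <= 0 or self.lambda_control <= 0:
            raise SynthSpecError("Poisson rates must be > 0")
        total = sum(self.context_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthSpecError(f"context_mix must sum to 1, sums to {total}")
        if self.notes_per_patient[0] < 1 or self.notes_per_patient[0] > self.notes_per_patient[1]:
            raise SynthSpecError("notes_per_patient must be a valid range >= 1")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "notes_per_patient": list(self.notes_per_patient),
            "disease_prevalence": self.disease_prevalence,
            "disease_groups": {k: list(v) for k, v in self.disease_groups.items()},
            "lambda_case": self.lambda_case,
            "lambda_control": self.lambda_control,
            "nonpositive_disease_rate": self.nonpositive_disease_rate,
            "background_rate": self.background_rate,
            "context_mix": self.context_mix,
            "section_layout": {k: list(v) for k, v in self.section_layout.items()},
            "note_type_weights": self.note_type_weights,
            "labs_per_summary": list(self.labs_per_summary),
            "extra_lab_values": list(self.extra_lab_values),
            "corruption_rate": self.corruption_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        for key in ("notes_per_patient", "labs_per_summary", "extra_lab_values"):
            if key in d:
                d[key] = tuple(d[key])
        if "disease_groups" in d:
            d["disease_groups"] = {k: tuple(v) for k, v in d["disease_groups"].items()}
        if "section_layout" in d:
            d["section_layout"] = {k: tuple(v) for k, v in d["section_layout"].items()}
        return cls(**d)


def perfect_recovery_spec(seed: int) -> SynthSpec:
    """100 patients, ~500 notes, no lab corruption: the recovery test bed."""
    return SynthSpec(seed=seed)


def hepatitis_c_study_spec(seed: int) -> SynthSpec:
    """A 200-patient hepatitis-C-shaped cohort (prevalence 33/200)."""
    return SynthSpec(
        seed=seed,
        n_patients=200,
        notes_per_patient=(2, 5),
        disease_prevalence={"C0019196": 33 / 200},
    )


def hiv_study_spec(seed: int) -> SynthSpec:
    """A 1000-patient HIV-shaped cohort (prevalence 76/1000).

    The two search concepts are not is-a related, so they form an explicit
    disease group.
    """
    return SynthSpec(
        seed=seed,
        n_patients=1000,
        notes_per_patient=(2, 5),
        disease_prevalence={"C0019699": 76 / 1000},
        disease_groups={"C0019699": ("C0019699", "C0920550")},
    )


@dataclass
class GroundTruth:
    """Gold annotations emitted alongside a generated corpus."""

    mentions: list[ConceptMention] = field(default_factory=list)
    sections: dict[str, list[SectionSpan]] = field(default_factory=dict)
    patient_labels: dict[str, dict[str, str]] = field(default_factory=dict)
    lab_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient_id", "name_source", "value"]
        )
    )
    written_measurements: list[dict] = field(default_factory=list)

    def note_ids(self) -> set[str]:
        return {m.note_id for m in self.mentions} | set(self.sections)

    def labels_for(self, root_cui: str) -> dict[str, str]:
        """patient_id -> "positive"/"unknown" for one study disease."""
        return {
            pid: labels[root_cui] for pid, labels in self.patient_labels.items()
        }

    def positive_counts(self, root_cui: str, group: Sequence[str]) -> dict[str, int]:
        """Gold per-patient positive-mention counts for a concept group."""
        cuis = set(group)
        counts = {pid: 0 for pid in self.patient_labels}
        pid_of = self._patient_of_note
        for m in self.mentions:
            if m.cui in cuis and categorize(m) == "positive":
                counts[pid_of[m.note_id]] += 1
        return counts

    # filled by generate(); maps note_id -> patient_id
    _patient_of_note: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mentions": [m.to_dict() for m in self.mentions],
            "sections": {
                nid: [vars(s) for s in spans]
                for nid, spans in sorted(self.sections.items())
            },
            "patient_labels": {k: self.patient_labels[k] for k in sorted(self.patient_labels)},
            "lab_table": self.lab_table.to_dict(orient="records"),
            "written_measurements": self.written_measurements,
            "patient_of_note": {k: self._patient_of_note[k] for k in sorted(self._patient_of_note)},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls(
            mentions=[ConceptMention.from_dict(m) for m in d["mentions"]],
            sections={
                nid: [SectionSpan(**s) for s in spans]
                for nid, spans in d["sections"].items()
            },
            patient_labels=d["patient_labels"],
            lab_table=pd.DataFrame(
                d["lab_table"], columns=["patient_id", "name_source", "value"]
            ),
            written_measurements=d["written_measurements"],
        )
        gt._patient_of_note = d["patient_of_note"]
        return gt

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_graph() -> OntologyGraph:
    """The bundled synthetic mini-UMLS."""
    return load_ontology(_DATA_DIR / "concepts.json", _DATA_DIR / "hierarchy.tsv")


# ---------------------------------------------------------------------------
# vocabulary safety checks
# ---------------------------------------------------------------------------

def _phrase_tokens(phrase: str) -> list[str]:
    return phrase.lower().split()


def _check_vocabularies(
    graph: OntologyGraph,
    lexicon: TriggerLexicon,
    rules: MeasurementRuleTable,
) -> None:
    """Filler must not be able to assemble any meaningful phrase, and every
    synonym must map to exactly one concept (so gold CUIs are unambiguous)."""
    filler = set(FILLER_VOCAB)
    phrases: list[str] = []
    for c in graph.concepts.values():
        phrases.extend(c.all_names())
    phrases.extend(e.phrase for e in lexicon.entries)
    phrases.extend(lexicon.terminators)
    for r in rules.rules:
        phrases.extend(r.aliases)
    clashes = [
        p for p in phrases if all(t in filler for t in _phrase_tokens(p))
    ]
    if clashes:
        raise SynthSpecError(f"filler vocabulary can assemble phrases: {clashes}")
    ambiguous = {
        name: cuis for name, cuis in graph.name_index.items() if len(cuis) > 1
    }
    if ambiguous:
        raise SynthSpecError(f"ambiguous synonyms break gold CUIs: {ambiguous}")


def _check_gen_triggers(lexicon: TriggerLexicon) -> None:
    have = {(e.phrase, e.value) for e in lexicon.entries if e.direction == "forward"}
    missing = [
        (p, v)
        for v, pool in _GEN_TRIGGERS.items()
        for p in pool
        if (p, v) not in have
    ]
    if missing:
        raise SynthSpecError(f"lexicon lacks generation triggers: {missing}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _MentionEvent:
    cui: str
    combo: str  # "negation|temporality|experiencer"


def _filler(rng: np.random.Generator, lo: int, hi: int) -> list[str]:
    k = int(rng.integers(lo, hi + 1))
    return [FILLER_VOCAB[int(i)] for i in rng.integers(0, len(FILLER_VOCAB), size=k)]


def _choice(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def _mention_sentence(
    rng: np.random.Generator, surface: str, combo: str
) -> tuple[str, int]:
    """Render one sentence containing exactly one concept surface form.

    Trigger order is experiencer, temporality, negation, then the phrase,
    so each forward trigger's 8-token scope is guaranteed to reach the
    phrase and greedy trigger matching cannot merge adjacent triggers.
    Returns the sentence text and the phrase's character offset within it.
    """
    negation, temporality, experiencer = combo.split("|")
    words = _filler(rng, 1, 3)
    if experiencer == "other":
        words.append(_choice(rng, _GEN_TRIGGERS["other"]))
    if temporality in ("historical", "hypothetical"):
        words.append(_choice(rng, _GEN_TRIGGERS[temporality]))
    if negation == "negated":
        words.append(_choice(rng, _GEN_TRIGGERS["negated"]))
    prefix = " ".join(words) + " "
    suffix_words = _filler(rng, 0, 2)
    suffix = (" " + " ".join(suffix_words) if suffix_words else "") + "."
    return prefix + surface + suffix, len(prefix)


def _sample_combo(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    combos = list(mix)
    probs = np.asarray([mix[c] for c in combos], dtype=float)
    probs /= probs.sum()
    return combos[int(rng.choice(len(combos), p=probs))]


_DEFAULT_COMBO = "affirmed|recent|patient"


def generate(
    spec: SynthSpec,
    graph: OntologyGraph | None = None,
    lexicon: TriggerLexicon | None = None,
    hd: HeadingDictionary | None = None,
    rules: MeasurementRuleTable | None = None,
) -> tuple[list[ClinicalNote], GroundTruth]:
    """Generate a corpus and its exact ground truth; deterministic in seed."""
    graph = graph if graph is not None else default_graph()
    lexicon = lexicon if lexicon is not None else TriggerLexicon.default()
    hd = hd if hd is not None else HeadingDictionary.default()
    rules = rules if rules is not None else MeasurementRuleTable.default()
    _check_vocabularies(graph, lexicon, rules)
    _check_gen_triggers(lexicon)

    referenced = set(spec.disease_prevalence) | {
        c for g in spec.disease_groups.values() for c in g
    }
    unknown = sorted(referenced - set(graph.concepts))
    if unknown:
        raise SynthSpecError(f"spec references unknown cuis: {unknown}")
    unknown_heads = sorted(
        {
            h
            for layout in spec.section_layout.values()
            for h in layout
            if h not in hd.canonical_labels
        }
    )
    if unknown_heads:
        raise SynthSpecError(f"spec references unknown headings: {unknown_heads}")

    groups: dict[str, list[str]] = {}
    for root in spec.disease_prevalence:
        if root in spec.disease_groups:
            groups[root] = sorted(spec.disease_groups[root])
        else:
            groups[root] = sorted({root} | graph.descendants(root))
    disease_cuis = {c for g in groups.values() for c in g}
    background_pool = sorted(set(graph.concepts) - disease_cuis)
    # only inject surface forms free of edge punctuation: the recognizer
    # trims mention spans to token cores, so "HIV+" would recover as "HIV"
    def _clean(name: str) -> bool:
        import re as _re

        return all(
            _re.sub(r"^[^\w]+|[^\w]+$", "", t) == t for t in name.split()
        )

    surfaces = {
        cui: (sorted(filter(_clean, graph.concepts[cui].all_names())) or
              sorted(graph.concepts[cui].all_names()))
        for cui in graph.concepts
    }
    nondefault_mix = {
        k: v for k, v in spec.context_mix.items() if k != _DEFAULT_COMBO
    }

    rng = np.random.default_rng(spec.seed)
    notes: list[ClinicalNote] = []
    truth = GroundTruth()
    lab_rows: list[tuple[str, str, float]] = []

    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        labels: dict[str, str] = {}
        events: list[_MentionEvent] = []
        for root, prevalence in sorted(spec.disease_prevalence.items()):
            is_case = bool(rng.random() < prevalence)
            labels[root] = "positive" if is_case else "unknown"
            lam = spec.lambda_case if is_case else spec.lambda_control
            n_pos = int(rng.poisson(lam))
            for _ in range(n_pos):
                events.append(
                    _MentionEvent(cui=_choice(rng, groups[root]), combo=_DEFAULT_COMBO)
                )
            n_nonpos = int(rng.poisson(spec.nonpositive_disease_rate))
            for _ in range(n_nonpos):
                events.append(
                    _MentionEvent(
                        cui=_choice(rng, groups[root]),
                        combo=_sample_combo(rng, nondefault_mix),
                    )
                )
        truth.patient_labels[pid] = labels

        lo, hi = spec.notes_per_patient
        n_notes = int(rng.integers(lo, hi + 1))
        other_types = sorted(spec.note_type_weights)
        type_probs = np.asarray(
            [spec.note_type_weights[t] for t in other_types], dtype=float
        )
        type_probs /= type_probs.sum()
        note_types = [
            other_types[int(rng.choice(len(other_types), p=type_probs))]
            for _ in range(n_notes - 1)
        ] + ["Discharge Summary"]
        day = _date(2019, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        note_dates = []
        for _ in range(n_notes):
            note_dates.append(day.isoformat())
            day += timedelta(days=int(rng.integers(5, 30)))

        # assign each disease event to a note; add per-note background events
        events_by_note: list[list[_MentionEvent]] = [[] for _ in range(n_notes)]
        for ev in events:
            events_by_note[int(rng.integers(0, n_notes))].append(ev)
        for j in range(n_notes):
            for _ in range(int(rng.poisson(spec.background_rate))):
                events_by_note[j].append(
                    _MentionEvent(
                        cui=_choice(rng, background_pool),
                        combo=_sample_combo(rng, spec.context_mix),
                    )
                )

        # plan lab measurements for discharge summaries (two passes so
        # corrupted written values can avoid the patient's full value list)
        lab_plan: dict[int, list[dict]] = {}
        structured: dict[str, list[float]] = {}
        for j, ntype in enumerate(note_types):
            if ntype != "Discharge Summary":
                continue
            k = int(rng.integers(spec.labs_per_summary[0], spec.labs_per_summary[1] + 1))
            chosen = rng.choice(len(rules.rules), size=min(k, len(rules.rules)), replace=False)
            plan = []
            for ridx in sorted(int(x) for x in chosen):
                rule = rules.rules[ridx]
                lo_v, hi_v = rule.plausible_range
                value = round(float(rng.uniform(lo_v, hi_v)), 1)
                structured.setdefault(rule.name_source, []).append(value)
                n_extra = int(
                    rng.integers(spec.extra_lab_values[0], spec.extra_lab_values[1] + 1)
                )
                for _ in range(n_extra):
                    structured[rule.name_source].append(
                        round(float(rng.uniform(lo_v, hi_v)), 1)
                    )
                plan.append({"rule": rule, "true_value": value})
            lab_plan[j] = plan
        for j, plan in lab_plan.items():
            for item in plan:
                rule = item["rule"]
                corrupted = bool(rng.random() < spec.corruption_rate)
                written = item["true_value"]
                if corrupted:
                    avoid = {round(v, 1) for v in structured[rule.name_source]}
                    lo_v, hi_v = rule.plausible_range
                    while round(written, 1) in avoid:
                        written = round(float(rng.uniform(lo_v, hi_v)), 1)
                item["written"] = written
                item["corrupted"] = corrupted
        for name_source in sorted(structured):
            for v in structured[name_source]:
                lab_rows.append((pid, name_source, v))

        # render notes
        for j in range(n_notes):
            note_id = f"{pid}-N{j:02d}"
            ntype = note_types[j]
            truth._patient_of_note[note_id] = pid
            layout = spec.section_layout.get(ntype, ())
            lines: list[tuple[str, dict | None]] = []  # (text, payload)
            if layout:
                per_section: dict[str, list[_MentionEvent]] = {s: [] for s in layout}
                for ev in events_by_note[j]:
                    per_section[layout[int(rng.integers(0, len(layout)))]].append(ev)
                for section_label in layout:
                    lines.append((section_label + ":", {"heading": section_label}))
                    content: list[tuple[str, dict | None]] = []
                    for ev in per_section[section_label]:
                        content.append((None, {"event": ev, "section": section_label}))
                    if section_label == "Hospital Discharge Physical":
                        for item in lab_plan.get(j, []):
                            content.append((None, {"lab": item}))
                    for _ in range(int(rng.integers(1, 3))):
                        content.append((" ".join(_filler(rng, 3, 8)) + ".", None))
                    order = rng.permutation(len(content))
                    lines.extend(content[int(o)] for o in order)
            else:
                content = [
                    (None, {"event": ev, "section": "unsectioned"})
                    for ev in events_by_note[j]
                ]
                for _ in range(int(rng.integers(1, 4))):
                    content.append((" ".join(_filler(rng, 3, 8)) + ".", None))
                order = rng.permutation(len(content))
                lines.extend(content[int(o)] for o in order)

            # materialize text with offsets and gold records
            text_parts: list[str] = []
            offset = 0
            heading_offsets: list[tuple[str, int]] = []
            pending_mentions: list[ConceptMention] = []
            for raw, payload in lines:
                if payload and "event" in payload:
                    ev = payload["event"]
                    surface = _choice(rng, surfaces[ev.cui])
                    line, rel = _mention_sentence(rng, surface, ev.combo)
                    neg, temp, exp = ev.combo.split("|")
                    pending_mentions.append(
                        ConceptMention(
                            note_id=note_id,
                            cui=ev.cui,
                            start=offset + rel,
                            end=offset + rel + len(surface),
                            surface=surface,
                            negation=neg,
                            temporality=temp,
                            experiencer=exp,
                            section=payload["section"],
                        )
                    )
                elif payload and "lab" in payload:
                    item = payload["lab"]
                    rule = item["rule"]
                    alias = _choice(rng, list(rule.aliases)).capitalize()
                    sep = _choice(rng, [": ", " - ", " was ", " of ", " "])
                    value_str = f"{item['written']:g}"
                    unit = f" {rule.unit}" if rng.random() < 0.5 and rule.unit else ""
                    line = f"{alias}{sep}{value_str}{unit}"
                    truth.written_measurements.append(
                        {
                            "note_id": note_id,
                            "name_umls": rule.name_umls,
                            "name_source": rule.name_source,
                            "value": item["written"],
                            "corrupted": item["corrupted"],
                        }
                    )
                else:
                    line = raw
                    if payload and "heading" in payload:
                        heading_offsets.append((payload["heading"], offset))
                text_parts.append(line)
                offset += len(line) + 1
            text = "\n".join(text_parts)
            spans = []
            for s_idx, (label, h_off) in enumerate(heading_offsets):
                end = (
                    heading_offsets[s_idx + 1][1]
                    if s_idx + 1 < len(heading_offsets)
                    else len(text)
                )
                spans.append(
                    SectionSpan(
                        heading_raw=label + ":",
                        heading_canonical=label,
                        start=h_off,
                        end=end,
                    )
                )
            truth.sections[note_id] = spans
            truth.mentions.extend(pending_mentions)
            notes.append(
                ClinicalNote(
                    patient_id=pid,
                    note_id=note_id,
                    date=note_dates[j],
                    note_type=ntype,
                    text=text,
                )
            )

    truth.lab_table = pd.DataFrame(
        lab_rows, columns=["patient_id", "name_source", "value"]
    )
    # self-consistency: every gold span re-extracts its surface
    text_of = {n.note_id: n.text for n in notes}
    for m in truth.mentions:
        assert text_of[m.note_id][m.start : m.end] == m.surface
    return notes, truth


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _prf(tp: int, n_sys: int, n_gold: int) -> dict[str, float]:
    p = tp / n_sys if n_sys else 0.0
    r = tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return {"precision": p, "recall": r, "f1": f, "tp": tp, "n_system": n_sys, "n_gold": n_gold}


def score_against_truth(system, truth: GroundTruth, layer: str, **kw) -> dict:
    """Score a pipeline layer against ground truth.

    layer="mentions": *system* is a list of ConceptMention; strict match on
    (note_id, span, cui, negation, temporality, experiencer).
    layer="sections": *system* is {note_id: [SectionSpan]}; strict match on
    (note_id, span, canonical label).
    layer="cohort": *system* is a list of CohortSummaryRow for the concept
    group given as ``cuis=``; compared against a recount from gold.
    layer="measurements": *system* is a list of Measurement; strict match
    on (note_id, canonical name, value to 1 decimal).
    layer="labels": *system* is {patient_id: label} for ``root_cui=``;
    reports accuracy.
    """
    known_notes = set(truth.note_ids()) | set(truth._patient_of_note)
    if layer == "mentions":
        bad = {m.note_id for m in system} - known_notes
        if bad:
            raise ValueError(f"unknown note_ids in system output: {sorted(bad)}")
        sys_set = {
            (m.note_id, m.start, m.end, m.cui, m.negation, m.temporality, m.experiencer)
            for m in system
        }
        gold_set = {
            (m.note_id, m.start, m.end, m.cui, m.negation, m.temporality, m.experiencer)
            for m in truth.mentions
        }
        return _prf(len(sys_set & gold_set), len(sys_set), len(gold_set))
    if layer == "sections":
        bad = set(system) - known_notes
        if bad:
            raise ValueError(f"unknown note_ids in system output: {sorted(bad)}")
        sys_set = {
            (nid, s.start, s.end, s.heading_canonical)
            for nid, spans in system.items()
            for s in spans
        }
        gold_set = {
            (nid, s.start, s.end, s.heading_canonical)
            for nid, spans in truth.sections.items()
            for s in spans
        }
        return _prf(len(sys_set & gold_set), len(sys_set), len(gold_set))
    if layer == "cohort":
        cuis = set(kw["cuis"])
        gold_counts: dict[str, dict[str, int]] = {}
        for m in truth.mentions:
            if m.cui in cuis:
                pid = truth._patient_of_note[m.note_id]
                per = gold_counts.setdefault(
                    pid,
                    {"positive": 0, "historical_hypothetical": 0, "negated": 0, "other_experiencer": 0},
                )
                per[categorize(m)] += 1
        gold_rows = {
            pid: (
                sum(per.values()),
                per["positive"],
                per["historical_hypothetical"],
                per["negated"],
                per["other_experiencer"],
            )
            for pid, per in gold_counts.items()
        }
        sys_rows = {
            r.patient_id: (r.n_total, r.n_positive, r.n_hist_hypo, r.n_negated, r.n_other)
            for r in system
        }
        tp = sum(1 for pid, row in sys_rows.items() if gold_rows.get(pid) == row)
        return _prf(tp, len(sys_rows), len(gold_rows))
    if layer == "measurements":
        bad = {ms.note_id for ms in system} - known_notes
        if bad:
            raise ValueError(f"unknown note_ids in system output: {sorted(bad)}")
        sys_set = {(ms.note_id, ms.name_umls, round(ms.value, 1)) for ms in system}
        gold_set = {
            (w["note_id"], w["name_umls"], round(w["value"], 1))
            for w in truth.written_measurements
        }
        return _prf(len(sys_set & gold_set), len(sys_set), len(gold_set))
    if layer == "labels":
        gold = truth.labels_for(kw["root_cui"])
        bad = set(system) - set(gold)
        if bad:
            raise ValueError(f"unknown patient_ids in system output: {sorted(bad)}")
        n = len(gold)
        correct = sum(1 for pid, lab in gold.items() if system.get(pid) == lab)
        return {"accuracy": correct / n if n else 0.0, "n": n}
    raise ValueError(f"unknown layer {layer!r}")
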