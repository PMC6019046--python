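"""Per-patient structured medical profiles and measurement extraction.

A medical profile summarizes one patient over one period as *aspects* —
groups of concept mentions keyed by canonical section label (medications,
past illness, family history, ...).  When the period contains a discharge
summary, the profile mirrors that document's detected sections; otherwise an
automated profile is assembled by routing each mention to an aspect from its
semantic type and context (an editable rule table).  The two sources are
always differentiated.

Free-text laboratory/vital-sign lines ("Sodium: 140", "White blood cells
8.2") are parsed against a measurement rule table and can be verified
against a structured lab-events table: an extraction is deemed correct when
its value appears among that patient's structured values for the same
measurement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .annotator import ClinicalNote, ConceptMention
from .doc_structure import HeadingDictionary, SectionSpan, detect_sections
from .ontology import OntologyGraph

__all__ = [
    "Measurement",
    "MeasurementRule",
    "MeasurementRuleTable",
    "MedicalProfile",
    "RoutingTable",
    "build_profile",
    "split_periods",
    "extract_measurements",
    "verify_measurements",
    "VerificationReport",
]

logger = logging.getLogger(__name__)
_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Measurement:
    """One parsed measurement value with provenance."""

    name_umls: str
    name_source: str
    value: float
    unit: str
    note_id: str
    span: tuple[int, int]


@dataclass(frozen=True)
class MeasurementRule:
    name_umls: str
    name_source: str
    aliases: tuple[str, ...]
    unit: str
    plausible_range: tuple[float, float]


_NUMBER = r"([0-9]+(?:\.[0-9]+)?)"


class MeasurementRuleTable:
    """Rule rows mapping measurement aliases to canonical names and ranges."""

    def __init__(self, rules: Sequence[MeasurementRule], scan_sections: Sequence[str]):
        self.rules = list(rules)
        self.scan_sections = list(scan_sections)
        self._patterns: list[tuple[MeasurementRule, re.Pattern]] = []
        for rule in self.rules:
            alias_alt = "|".join(
                re.escape(a) for a in sorted(rule.aliases, key=len, reverse=True)
            )
            # alias, then a separator (colon, dash, "of", "was", "is", or
            # bare whitespace), then the numeric value and an optional unit
            pat = re.compile(
                rf"(?<![A-Za-z])(?:{alias_alt})\s*(?:[:\-]\s*|\bof\s+|\bwas\s+|\bis\s+)?"
                rf"{_NUMBER}(?:\s*({re.escape(rule.unit)}))?",
                re.IGNORECASE,
            )
            self._patterns.append((rule, pat))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MeasurementRuleTable":
        raw = yaml.safe_load(Path(path).read_text())
        rules = [
            MeasurementRule(
                name_umls=r["name_umls"],
                name_source=r["name_source"],
                aliases=tuple(r["aliases"]),
                unit=r.get("unit", ""),
                plausible_range=tuple(r["plausible_range"]),
            )
            for r in raw["measurements"]
        ]
        return cls(rules, raw.get("scan_sections", []))

    @classmethod
    def default(cls) -> "MeasurementRuleTable":
        global _default_rules
        if _default_rules is None:
            _default_rules = cls.from_yaml(_DATA_DIR / "measurements.yaml")
        return _default_rules


_default_rules: "MeasurementRuleTable | None" = None


def extract_measurements(
    note: ClinicalNote,
    rules: MeasurementRuleTable | None = None,
    sections: list[SectionSpan] | None = None,
    hd: HeadingDictionary | None = None,
) -> list[Measurement]:
    """Parse measurement values from a note's lab-like sections.

    Only sections whose canonical label is in the rule table's
    ``scan_sections`` are scanned, line by line.  Parsed values outside a
    rule's plausible range are dropped (and logged), never reported.
    """
    if rules is None:
        rules = MeasurementRuleTable.default()
    if sections is None:
        sections = detect_sections(note, hd)
    scan: list[tuple[int, int]] = [
        (s.start, s.end)
        for s in sections
        if s.heading_canonical in rules.scan_sections
    ]
    out: list[Measurement] = []
    for lo, hi in scan:
        block = note.text[lo:hi]
        line_off = 0
        for line in block.split("\n"):
            for rule, pat in rules._patterns:
                for m in pat.finditer(line):
                    value = float(m.group(1))
                    if not (rule.plausible_range[0] <= value <= rule.plausible_range[1]):
                        logger.info(
                            "dropping implausible %s=%s in %s",
                            rule.name_umls, value, note.note_id,
                        )
                        continue
                    span = (
                        lo + line_off + m.start(1),
                        lo + line_off + m.end(1),
                    )
                    out.append(
                        Measurement(
                            name_umls=rule.name_umls,
                            name_source=rule.name_source,
                            value=value,
                            unit=m.group(2) or "",
                            note_id=note.note_id,
                            span=span,
                        )
                    )
            line_off += len(line) + 1
    out.sort(key=lambda ms: ms.span)
    return out


@dataclass
class VerificationReport:
    """Per-measurement verification counts against structured data."""

    table: pd.DataFrame  # name_umls, name_source, n_correct, n_incorrect,
    #                      n_unverifiable, n_total, accuracy_pct

    @property
    def average_accuracy(self) -> float:
        """Unweighted mean of per-measurement accuracies (verifiable rows)."""
        acc = self.table["accuracy_pct"].dropna()
        return float(acc.mean()) if len(acc) else float("nan")

    @property
    def overall_accuracy(self) -> float:
        """Pooled accuracy over all verifiable extractions."""
        c = int(self.table["n_correct"].sum())
        i = int(self.table["n_incorrect"].sum())
        return 100.0 * c / (c + i) if c + i else float("nan")


def _values_equal(a: float, b: float) -> bool:
    # mechanical stand-in for manual adjudication of rounding mismatches
    return round(a, 1) == round(b, 1)


def verify_measurements(
    extracted: Sequence[Measurement],
    structured: pd.DataFrame,
    note_patient: Mapping[str, str],
    converters: Mapping[str, Callable[[float, str], float]] | None = None,
) -> VerificationReport:
    """Label each extraction correct/incorrect against structured lab data.

    An extraction is correct when its value appears within the list of the
    same patient's structured values for that measurement (equality after
    rounding both sides to one decimal; optional per-measurement unit
    converters are applied first).  Measurements absent from the structured
    table are "unverifiable" and excluded from the accuracy denominator.

    *structured* needs columns ``patient_id``, ``name_source``, ``value``.
    """
    converters = converters or {}
    by_key: dict[tuple[str, str], list[float]] = {}
    for _, row in structured.iterrows():
        by_key.setdefault(
            (str(row["patient_id"]), str(row["name_source"])), []
        ).append(float(row["value"]))
    names_present = {k[1] for k in by_key}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for ms in extracted:
        key = (ms.name_umls, ms.name_source)
        c = counts.setdefault(
            key, {"n_correct": 0, "n_incorrect": 0, "n_unverifiable": 0}
        )
        if ms.name_source not in names_present:
            c["n_unverifiable"] += 1
            continue
        value = ms.value
        if ms.name_umls in converters:
            value = converters[ms.name_umls](value, ms.unit)
        pool = by_key.get((note_patient[ms.note_id], ms.name_source), [])
        if any(_values_equal(value, v) for v in pool):
            c["n_correct"] += 1
        else:
            c["n_incorrect"] += 1
    records = []
    for (name_umls, name_source), c in sorted(counts.items()):
        denom = c["n_correct"] + c["n_incorrect"]
        records.append(
            {
                "name_umls": name_umls,
                "name_source": name_source,
                **c,
                "n_total": denom + c["n_unverifiable"],
                "accuracy_pct": 100.0 * c["n_correct"] / denom if denom else float("nan"),
            }
        )
    table = pd.DataFrame(
        records,
        columns=[
            "name_umls", "name_source", "n_correct", "n_incorrect",
            "n_unverifiable", "n_total", "accuracy_pct",
        ],
    )
    return VerificationReport(table=table)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class RoutingTable:
    """Ordered aspect-routing rules for automated profiles."""

    rules: list[dict] = field(default_factory=list)
    default_route: str = "Other"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RoutingTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(rules=list(raw["rules"]), default_route=raw["default_route"])

    @classmethod
    def default(cls) -> "RoutingTable":
        return cls.from_yaml(_DATA_DIR / "routing.yaml")

    def route(self, mention: ConceptMention, semantic_type: str) -> str:
        for rule in self.rules:
            match = rule["match"]
            if "semantic_type" in match and semantic_type not in match["semantic_type"]:
                continue
            if "temporality" in match and mention.temporality not in match["temporality"]:
                continue
            if "experiencer" in match and mention.experiencer not in match["experiencer"]:
                continue
            return rule["route"]
        return self.default_route


@dataclass
class MedicalProfile:
    """A per-patient, per-period sectioned summary with measurements."""

    patient_id: str
    period_start: str
    period_end: str
    source: str  # "discharge_summary" | "automated"
    aspects: dict[str, list[ConceptMention]] = field(default_factory=dict)
    measurements: list[Measurement] = field(default_factory=list)

    def to_composition(self) -> dict:
        """A FHIR-Composition-shaped dict (informative, not conformant)."""
        return {
            "resourceType": "Composition",
            "subject": self.patient_id,
            "period": {"start": self.period_start, "end": self.period_end},
            "source": self.source,
            "section": [
                {
                    "title": label,
                    "entry": [m.to_dict() for m in mentions],
                }
                for label, mentions in sorted(self.aspects.items())
            ],
            "measurements": [
                {
                    "name_umls": ms.name_umls,
                    "name_source": ms.name_source,
                    "value": ms.value,
                    "unit": ms.unit,
                    "note_id": ms.note_id,
                    "span": list(ms.span),
                }
                for ms in self.measurements
            ],
        }


def split_periods(notes: Sequence[ClinicalNote]) -> list[tuple[str, str]]:
    """Segment a record into periods by discharge-summary dates.

    Each discharge summary closes a period (an inpatient episode ends with
    its summary); notes after the last summary form a trailing period.  A
    record with no discharge summary is one period.
    """
    if not notes:
        return []
    dates = sorted(n.date for n in notes)
    ds_dates = sorted({n.date for n in notes if n.note_type == "Discharge Summary"})
    if not ds_dates:
        return [(dates[0], dates[-1])]
    periods: list[tuple[str, str]] = []
    start = dates[0]
    for d in ds_dates:
        if start <= d:
            periods.append((start, d))
            start = (_date.fromisoformat(d) + timedelta(days=1)).isoformat()
    if start <= dates[-1]:
        periods.append((start, dates[-1]))
    return periods


def build_profile(
    patient_id: str,
    notes: Sequence[ClinicalNote],
    mentions_by_note: Mapping[str, Sequence[ConceptMention]],
    period: tuple[str, str],
    graph: OntologyGraph,
    routing: RoutingTable | None = None,
    rules: MeasurementRuleTable | None = None,
    hd: HeadingDictionary | None = None,
) -> MedicalProfile:
    """Build one patient's profile for one period.

    Mentions must already be contextualized and section-assigned.  If the
    period contains a discharge summary, the profile mirrors the latest
    one's sections (source ``discharge_summary``) and measurements are
    extracted from its lab-like sections; otherwise every period mention is
    routed to an aspect by the routing table (source ``automated``).
    """
    if routing is None:
        routing = RoutingTable.default()
    lo, hi = period
    in_period = [n for n in notes if n.patient_id == patient_id and lo <= n.date <= hi]
    summaries = sorted(
        (n for n in in_period if n.note_type == "Discharge Summary"),
        key=lambda n: (n.date, n.note_id),
    )
    profile = MedicalProfile(
        patient_id=patient_id, period_start=lo, period_end=hi, source="automated"
    )
    if summaries:
        ds = summaries[-1]
        profile.source = "discharge_summary"
        for m in mentions_by_note.get(ds.note_id, []):
            profile.aspects.setdefault(m.section, []).append(m)
        profile.measurements = extract_measurements(ds, rules, hd=hd)
        return profile
    for note in sorted(in_period, key=lambda n: (n.date, n.note_id)):
        for m in mentions_by_note.get(note.note_id, []):
            stype = graph.concepts[m.cui].semantic_type if m.cui in graph else ""
            profile.aspects.setdefault(routing.route(m, stype), []).append(m)
    return profile
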