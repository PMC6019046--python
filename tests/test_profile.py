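import dataclasses

import pandas as pd
import pytest
from scipy.stats import binom

from semehr_lite.annotator import ConceptMention
from semehr_lite.ontology import Concept, OntologyGraph
from semehr_lite.profile import (
    MeasurementRuleTable,
    build_profile,
    extract_measurements,
    split_periods,
    verify_measurements,
)
from semehr_lite.synthcorpus import generate, perfect_recovery_spec


TABLE_MEASUREMENTS = [
    "Hematocrit", "Platelets", "Sodium",
    "Mean corpuscular hemoglobin concentration", "Alanine aminotransferase",
    "Red blood cell distribution width", "Serum aspartate aminotransferase",
    "Chloride", "Blood urea", "Leukocytes", "Glucose",
]


def _ds_note(note_factory, body):
    return note_factory(
        "Hospital Discharge Physical:\n" + body, note_type="Discharge Summary"
    )


class TestExtract:
    def test_rule_table_covers_the_11_measurements(self):
        rules = MeasurementRuleTable.default()
        assert {r.name_umls for r in rules.rules} == set(TABLE_MEASUREMENTS)

    @pytest.mark.parametrize(
        "line,name_umls,value",
        [
            ("Sodium: 140", "Sodium", 140.0),
            ("White blood cells 8.2", "Leukocytes", 8.2),
            ("Urea nitrogen was 14", "Blood urea", 14.0),
            ("Hematocrit - 41.5 %", "Hematocrit", 41.5),
            ("Glucose of 98 mg/dL", "Glucose", 98.0),
        ],
    )
    def test_line_patterns(self, note_factory, line, name_umls, value):
        (m,) = extract_measurements(_ds_note(note_factory, line))
        assert (m.name_umls, m.value) == (name_umls, value)

    def test_source_label_mapping(self, note_factory):
        (m,) = extract_measurements(_ds_note(note_factory, "White blood cells 8.2"))
        assert m.name_source == "White blood cells"

    def test_implausible_value_dropped(self, note_factory):
        assert extract_measurements(_ds_note(note_factory, "Sodium: 9999")) == []

    def test_only_configured_sections_scanned(self, note_factory):
        note = note_factory(
            "History of Present Illness:\nSodium: 140", note_type="Discharge Summary"
        )
        assert extract_measurements(note) == []

    def test_span_reparses_to_value(self, note_factory):
        note = _ds_note(note_factory, "Sodium: 140\nWhite blood cells 8.2")
        for m in extract_measurements(note):
            assert float(note.text[m.span[0] : m.span[1]]) == m.value


class TestVerify:
    def _structured(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "name_source", "value"])

    def _measurement(self, value, name_umls="Sodium", name_source="Sodium"):
        from semehr_lite.profile import Measurement

        return Measurement(name_umls, name_source, value, "", "N1", (0, 1))

    def test_membership_is_correct(self):
        rep = verify_measurements(
            [self._measurement(140.0)],
            self._structured([("P1", "Sodium", 138), ("P1", "Sodium", 140), ("P1", "Sodium", 142)]),
            {"N1": "P1"},
        )
        assert rep.table.iloc[0]["n_correct"] == 1

    def test_rounding_tolerance(self):
        rep = verify_measurements(
            [self._measurement(140.04)],
            self._structured([("P1", "Sodium", 140.0)]),
            {"N1": "P1"},
        )
        assert rep.table.iloc[0]["n_correct"] == 1

    def test_mismatch_is_incorrect(self):
        rep = verify_measurements(
            [self._measurement(141.0)],
            self._structured([("P1", "Sodium", 140.0)]),
            {"N1": "P1"},
        )
        assert rep.table.iloc[0]["n_incorrect"] == 1

    def test_unverifiable_excluded_from_denominator(self):
        rep = verify_measurements(
            [self._measurement(5.0, "Leukocytes", "White blood cells"),
             self._measurement(140.0)],
            self._structured([("P1", "Sodium", 140.0)]),
            {"N1": "P1"},
        )
        row = rep.table.set_index("name_umls").loc["Leukocytes"]
        assert row["n_unverifiable"] == 1 and pd.isna(row["accuracy_pct"])
        assert rep.average_accuracy == 100.0

    def test_average_is_unweighted_mean_of_measurement_accuracies(self):
        rep = verify_measurements(
            [self._measurement(140.0), self._measurement(141.0),
             self._measurement(8.2, "Leukocytes", "White blood cells")],
            self._structured([("P1", "Sodium", 140.0),
                              ("P1", "White blood cells", 8.2)]),
            {"N1": "P1"},
        )
        # Sodium 50%, Leukocytes 100% -> unweighted mean 75
        assert rep.average_accuracy == pytest.approx(75.0)
        assert rep.overall_accuracy == pytest.approx(100 * 2 / 3)

    def test_zero_corruption_gives_perfect_accuracy(self, recovery_corpus):
        truth = recovery_corpus["truth"]
        extracted = [
            m for n in recovery_corpus["notes"] for m in extract_measurements(n)
        ]
        rep = verify_measurements(extracted, truth.lab_table, truth._patient_of_note)
        assert rep.overall_accuracy == 100.0

    def test_corrupted_corpus_accuracy_in_binomial_band(self):
        """With 10% corruption the verified share falls in the exact
        binomial 99% interval around 90%."""
        spec = dataclasses.replace(perfect_recovery_spec(5), corruption_rate=0.1)
        notes, truth = generate(spec)
        extracted = [m for n in notes for m in extract_measurements(n)]
        assert len(extracted) >= 200
        rep = verify_measurements(extracted, truth.lab_table, truth._patient_of_note)
        n = len(extracted)
        lo = binom.ppf(0.005, n, 0.9) / n * 100
        hi = binom.ppf(0.995, n, 0.9) / n * 100
        assert lo <= rep.overall_accuracy <= hi


class TestProfiles:
    @pytest.fixture()
    def small_graph(self):
        return OntologyGraph(
            [
                Concept("C1", "ribavirin", semantic_type="Pharmacologic Substance"),
                Concept("C2", "hepatitis C", semantic_type="Disease or Syndrome"),
                Concept("C3", "smoking", semantic_type="Individual Behavior"),
            ]
        )

    def _mention(self, note_id, cui, **kw):
        return ConceptMention(note_id, cui, 0, 1, "x", **kw)

    def test_discharge_summary_passthrough(self, note_factory, graph):
        ds = note_factory("PMH:\nhepatitis C.", note_id="DS1",
                          note_type="Discharge Summary")
        m = self._mention("DS1", "C0019196", section="History of Past Illness")
        prof = build_profile("P1", [ds], {"DS1": [m]}, ("2020-01-01", "2020-12-31"), graph)
        assert prof.source == "discharge_summary"
        assert prof.aspects == {"History of Past Illness": [m]}

    def test_automated_routing(self, note_factory, small_graph):
        note = note_factory("text", note_id="N1")
        mentions = [
            self._mention("N1", "C1"),
            self._mention("N1", "C2", temporality="historical"),
            self._mention("N1", "C2", experiencer="other"),
            self._mention("N1", "C3"),
            self._mention("N1", "C2"),
        ]
        prof = build_profile("P1", [note], {"N1": mentions},
                             ("2020-01-01", "2020-12-31"), small_graph)
        assert prof.source == "automated"
        assert [m.cui for m in prof.aspects["Admission Medications"]] == ["C1"]
        assert len(prof.aspects["History of Past Illness"]) == 1
        assert len(prof.aspects["Family History"]) == 1
        assert len(prof.aspects["Social History"]) == 1
        assert len(prof.aspects["Other"]) == 1

    def test_empty_period(self, graph):
        prof = build_profile("P1", [], {}, ("2020-01-01", "2020-01-02"), graph)
        assert prof.source == "automated" and prof.aspects == {}

    def test_profile_never_invents_mentions(self, note_factory, graph):
        ds = note_factory("PMH:\nhepatitis C.", note_id="DS1",
                          note_type="Discharge Summary")
        ms = [self._mention("DS1", "C0019196", section="History of Past Illness")]
        prof = build_profile("P1", [ds], {"DS1": ms}, ("2020-01-01", "2020-12-31"), graph)
        pool = set(id(m) for m in ms)
        for aspect in prof.aspects.values():
            assert all(id(m) in pool for m in aspect)

    def test_split_periods_by_discharge_dates(self, note_factory):
        notes = [
            note_factory("a", note_id="N1", date="2020-01-05"),
            note_factory("b", note_id="N2", date="2020-02-01",
                         note_type="Discharge Summary"),
            note_factory("c", note_id="N3", date="2020-03-10"),
        ]
        assert split_periods(notes) == [
            ("2020-01-05", "2020-02-01"),
            ("2020-02-02", "2020-03-10"),
        ]

    def test_split_periods_without_discharge(self, note_factory):
        notes = [note_factory("a", date="2020-01-05"), note_factory("b", date="2020-03-01")]
        assert split_periods(notes) == [("2020-01-05", "2020-03-01")]
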