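# semehr-lite

Desk-scale semantic search and information extraction over free-text
clinical notes. Most of what an electronic health record says about a
patient — diagnoses, symptoms, family history, lab values — lives in
narrative text, not in structured fields. `semehr-lite` turns a corpus of
clinical notes into a queryable, patient-centric resource:

1. **Concept annotation** — a gazetteer recognizer links text spans to
   UMLS-style concepts (CUIs), and a ConText/NegEx-style trigger-scope
   algorithm attaches three context dimensions to every mention:
   *negation* (affirmed/negated), *temporality* (recent/historical/
   hypothetical) and *experiencer* (patient/other).
2. **Document structure** — headed sections of discharge summaries are
   detected and mapped onto a canonical 31-label section set (23 FHIR
   CCDA discharge-summary sections plus 8 configurable extensions), so
   queries can be section-constrained ("family history of hepatitis C").
3. **Semantic indexing and cohort queries** — an inverted index serves
   ontology-expanded queries (a search for *liver disease* automatically
   includes its is-a descendants) and returns one summary row per patient
   with the four contextualized mention counts.
4. **Profiles and measurements** — per-period, FHIR-sectioned medical
   profiles per patient, plus rule-based extraction of laboratory values
   ("White blood cells 8.2") verified against a structured lab table.
5. **Study layer** — per-study post-filter rules over annotations and a
   patient classifier that uses a single feature, the number of positive
   mentions n⁺ of the query concepts in a patient's record, fitted either
   as a Gaussian naive Bayes model or as a count threshold
   (predict *case* iff n⁺ ≥ t), evaluated by stratified k-fold CV.

It is aimed at clinical-informatics researchers who want an auditable,
fully deterministic pipeline they can run on a laptop. Everything is
rule-based; there are no trained models, no services, and no external
downloads: a bundled synthetic-corpus generator emulates notes, ontology,
lab tables and gold annotations, which is also how the test suite
validates every stage.

## Worked example

Generate a 100-patient synthetic corpus, annotate it, and query a cohort:

```bash
semehr-lite simulate --preset perfect --seed 1 -o corpus
# 514 notes -> corpus
semehr-lite annotate --notes corpus/notes.jsonl -o mentions.jsonl
# annotated 514 notes -> mentions.jsonl
semehr-lite index build --notes corpus/notes.jsonl --mentions mentions.jsonl -o index.json
# indexed 514 notes -> index.json
semehr-lite query --index index.json --term "hepatitis C" --expand -o cohort.csv
# 67 patients -> cohort.csv
head -3 cohort.csv
# patient_id,total,positive,hist_hypo,negated,other
# P00065,9,8,0,1,0
# P00032,8,6,1,1,0
```

The query matched the term to its concept, expanded it with its is-a
descendants (chronic/viral hepatitis C), and summarized each matching
patient: P00065 has 9 mentions of the concept set — 8 positive (affirmed,
current, about the patient) and 1 negated. Constraining the search field
to a section returns, e.g., only patients whose *Family History* section
mentions the disease:

```bash
semehr-lite query --index index.json --term "hepatitis C" --expand \
    --section "Family History" -o fh.csv
# 3 patients -> fh.csv
```

Free-text lab values are extracted and verified against the structured
lab-events table the generator emitted alongside the notes:

```bash
semehr-lite measurements --notes corpus/notes.jsonl --verify corpus/labevents.csv -o verify.csv
# average accuracy 100.00% -> verify.csv
```

Finally, the study layer classifies patients from their positive-mention
count (here on the same corpus, using the generator's gold case/control
labels):

```bash
semehr-lite classify --cohort cohort.csv --labels corpus/labels.csv \
    --model naive_bayes --folds 10 --seed 7 -o metrics.csv
# weighted F 1.000 -> metrics.csv
cat metrics.csv
# class,precision,recall,f_measure,support
# positive,1.0000,1.0000,1.0000,16
# unknown,1.0000,1.0000,1.0000,84
# Weighted avg.,1.0000,1.0000,1.0000,100
```

On this clean synthetic corpus the 16 cases separate perfectly from the
84 controls; the methods note discusses what that does and does not say
about real clinical text.

## Configuration

All linguistic/clinical resources are editable packaged files under
`src/semehr_lite/data/`: the concept dictionary (`concepts.json`) and is-a
hierarchy (`hierarchy.tsv`), the trigger lexicon (`triggers.yaml`), the
heading dictionary (`headings.yaml`), the measurement rule table
(`measurements.yaml`), the automated-profile routing table
(`routing.yaml`) and document-type keywords (`doc_types.yaml`). Each CLI
command accepts overrides. `docs/methods.md` documents the algorithms,
parameters and the synthetic-spec YAML schema.
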