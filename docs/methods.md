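# Methods

This note documents the algorithms, their assumptions, the tunable
parameters, and the design decisions behind `semehr-lite`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Concept model and ontology reasoning

Concepts are mini-UMLS nodes: a CUI, a preferred name, synonyms, a
semantic type, source-vocabulary codes and a set of is-a parents. The
hierarchy is a poly-hierarchy (a DAG; SNOMED-style multiple parents are
allowed) and is validated at load time: cycles are rejected with the
offending edge list, dangling parents with the CUI named.

Query translation follows three steps: exact term matching against the
synonym index, subsumption expansion, and EHR-based exclusion. Term and
synonym normalization is NFKC, case-fold, whitespace collapse, and edge
punctuation stripping — exact match after normalization, deliberately
with **no fuzzy matching**: a fuzzy matcher needs a similarity threshold
with no principled setting, and exact-after-normalization keeps every
match auditable. Expansion is the transitive is-a descendant closure
(computed via `networkx` reachability); no other relation is followed,
because subsumption is the one inference cohort queries need ("chronic
hepatitis C *is a* hepatitis C"). Expansion is monotone and idempotent,
and the tests check it against an independent breadth-first closure on
random DAGs. EHR-based exclusion intersects a candidate set with the
CUIs that actually occur in the built index.

The bundled dictionary (23 concepts, `data/concepts.json`) is a
synthetic mini-UMLS sufficient for the shipped study shapes; it is a
data file, not code, and can be replaced wholesale.

## Annotation

**Segmentation.** Newlines always end a sentence (clinical notes are
line-oriented: headings, list items); within a line, runs of `.!?`
followed by whitespace close one. Tokens are maximal non-whitespace
runs. All offsets are 0-based half-open character offsets into the raw
text, so `surface == text[start:end]` round-trips.

**Recognition.** Greedy longest-match of dictionary synonyms over token
sequences, case-insensitive, left-to-right, non-overlapping. Mention
spans are trimmed to token cores, so in "fever." the mention is
`fever`, not `fever.`. When one surface form maps to several concepts
the tie-break is: prefer the concept whose preferred name equals the
surface form (after normalization), else the lexicographically lowest
CUI. This replaces a learned disambiguator with a rule that is stable,
documented and testable; it is wrong exactly when a non-preferred sense
is intended, which the bundled dictionary avoids by keeping synonyms
unambiguous.

**Context.** A ConText/NegEx-style trigger-scope algorithm. Each
trigger phrase carries a dimension (negation/temporality/experiencer), a
value, a direction (forward/backward/bidirectional) and a scope cap.
A forward trigger's scope runs from the token after it to the sentence
end, the first terminator ("but", "however", ...), or `scope_limit`
tokens — the default cap is **8 tokens**, the conventional window for
trigger-scope negation detectors; uncapped scopes over-negate long
coordinated sentences. Triggers apply in sentence order, so when two
scopes of the same dimension cover a mention the nearer (later) trigger
wins; the three dimensions are independent. The packaged lexicon
(`data/triggers.yaml`) has ~39 negation, ~18 temporality and ~16
experiencer triggers. "Hypothetical" is a temporality value (triggers
like "risk of", "rule out") so that history and hypothetical mentions
can share one report column. Defaults are affirmed/recent/patient.

**Categories.** The three dimensions fold into four mutually exclusive
categories with precedence `other_experiencer > negated >
historical_hypothetical > positive`; *positive* requires affirmed ∧
recent ∧ patient. The precedence resolves e.g. "mother does not have
hepatitis C" to the family-history category rather than the negated one:
who experienced the finding matters more for cohort building than its
polarity. By construction the four category counts always sum to the
total mention count.

## Document structure

A heading is a whole line matching
`^\s*[A-Za-z][A-Za-z /&-]{1,60}:\s*$` or an all-caps variant; each
heading opens a span closed by the next heading or end of text, so every
character after the first heading belongs to exactly one section.
Headings canonicalize through an alias table into a 31-label set: the 23
FHIR CCDA discharge-summary sections plus 8 extensions (laboratory
results, admission/discharge diagnosis, surgical history, physical
examination, assessment and plan, impression, follow-up). The extension
list is an explicit, editable stand-in — there is no authoritative
published set — and unmapped headings map to "Other" rather than being
dropped, so no text is orphaned. Document types come from note metadata
when present, else keyword rules over the first 500 characters, else
"Unknown".

## Profiles and measurements

A profile summarizes one patient over one period as aspects keyed by
canonical section label. Periods are segmented by discharge-summary
dates (each summary closes an inpatient episode; trailing notes form a
final period; a record with no summary is one period). If a period
contains a discharge summary the profile mirrors the latest one's
detected sections (`source=discharge_summary`); otherwise
(`source=automated`) each mention routes to an aspect through an ordered
rule table (`data/routing.yaml`): drugs → Admission Medications;
historical diseases/symptoms → History of Past Illness; other-experiencer
mentions → Family History; individual behaviors → Social History;
remainder → Other. The routing table is a reconstruction consistent
with the semantic types that dominate those sections in practice, and is
shipped as data precisely because it is a judgment call.

Measurement extraction scans lab-like sections (Hospital Discharge
Physical, Laboratory Results, Vital Signs, Other) line by line with one
pattern per measurement: alias, separator (colon, dash, "of", "was",
"is", or whitespace), number, optional unit. The rule table covers 11
common laboratory measurements (hematocrit, platelets, sodium, MCHC,
ALT, RDW, AST, chloride, blood urea, leukocytes, glucose) with their
source-system aliases and a plausible range each; out-of-range parses
are dropped and logged, never reported.

Verification declares an extraction correct iff its value appears among
the same patient's structured values for that measurement, with equality
after rounding both sides to one decimal and an optional per-measurement
unit-conversion hook — the two mechanical causes of spurious mismatches
(decimal rounding, unit differences) are thus absorbed by the comparison
rule rather than by manual adjudication. Measurements absent from the
structured table are counted separately as unverifiable and excluded
from the accuracy denominator. The report gives per-measurement counts
and accuracy; the summary "average accuracy" is the unweighted mean over
measurements, and a pooled overall accuracy is also provided.

## Index and cohort queries

The index is an in-process inverted map CUI → postings (patient, note,
offsets, category, section, date), persisted to one JSON file. A search
engine cluster would add operational weight without changing the query
contract, which is the part that matters at desk scale. Incremental
note addition and batch build produce identical indexes (tested).
A cohort query takes a concept set plus optional category, section and
date filters; membership needs ≥ 1 passing mention (no minimum-count
threshold — thresholding is the classifier's job); counts are split by
category so the partition invariant holds per row. Rows sort by total
descending, patient id ascending; longitudinal views sort notes by date
then note id. All tie-breaks are fixed for reproducibility.

## Study layer

Post-filter rules target either the mention's exact surface string or a
character window around it, with actions remove / set-negated /
set-other-experiencer / scale-confidence. Rules compile at load time
(an invalid regex can never fail mid-apply) and apply in list order;
remove-only rule sets are idempotent. The confidence field exists so
that downstream consumers can weight mentions; nothing in this package
lowers it except explicit rules.

The patient classifier uses one feature: n⁺, the patient's count of
positive mentions of the query concepts.

* `naive_bayes`: per-class Gaussian over n⁺ with a variance floor of
  1e-6 (degenerate single-valued classes otherwise produce infinite
  densities) and empirical class priors. A Gaussian event model is the
  standard single-numeric-feature choice; the decision table brackets it
  from the nonparametric side.
* `decision_table`: the integer threshold t maximizing training
  accuracy for "predict case iff n⁺ ≥ t", ties to the smaller t. The
  class with the larger mean count sits above the threshold.

Evaluation is stratified k-fold cross-validation (default k=10) with a
mandatory seed; predictions are pooled across folds and per-class
precision/recall/F plus the support-weighted average reported
(zero-division scores 0 with a warning). `analytic_bayes_threshold`
computes the accuracy-optimal threshold for a two-Poisson mixture by
exhaustive scan, which is what the fitted decision table should recover
as n grows.

## Synthetic corpora

The generator exists because the corpora this kind of system is
deployed on are access-restricted. It emulates: per-patient note
timelines (one discharge summary per patient, the rest progress
notes/radiology/GP letters), sectioned discharge summaries, concept
mentions with controlled context combinations, free-text lab lines with
a matching structured lab-events table, and per-patient case/control
labels. Notes are composed only of dictionary surface forms, lexicon
trigger phrases, canonical headings, measurement lines and a closed
30-token filler vocabulary; at generation time it is verified that no
meaningful phrase can be assembled from filler tokens alone and that
every synonym maps to a unique concept. One sentence per line, one
injected mention per sentence, and a fixed trigger order (experiencer,
temporality, negation, phrase) guarantee that trigger scopes cover
exactly the intended mention — so the emitted gold annotations are exact
by construction and perfect recovery is an achievable target, which is
what makes end-to-end F = 1.0 a meaningful regression test rather than a
vague aspiration.

Key spec parameters (YAML keys mirror the `SynthSpec` dataclass):

| parameter | default | meaning |
|---|---|---|
| `n_patients`, `notes_per_patient` | 100, (4, 6) | corpus shape (~500 notes) |
| `disease_prevalence` | {C0019196: 0.165} | P(case) per study disease |
| `lambda_case`, `lambda_control` | 3.0, 0.001 | Poisson rates for positive disease mentions per record |
| `nonpositive_disease_rate` | 0.8 | Poisson rate of negated/historical/family disease mentions (all patients) |
| `background_rate` | 1.5 | Poisson rate of non-disease mentions per note |
| `context_mix` | 55% positive combo | distribution over the 12 context combinations |
| `labs_per_summary` | (3, 7) | lab lines per discharge summary |
| `corruption_rate` | 0.0 | P(written lab value disagrees with the structured table) |

Rate rationale: a case typically accumulates a handful of positive
disease mentions across a record (λ_case = 3), while controls
essentially never carry a *positive* mention of a disease they do not
have — their disease mentions are negated, hypothetical or about family
members, which the generator injects separately for all patients. The
control rate is therefore small but nonzero (λ_control = 0.001),
representing rare documentation noise. Under these rates the
accuracy-optimal count threshold is t = 1 with a wide margin, and the
two shipped study shapes (200 patients at prevalence 33/200 for the
hepatitis-C cohort; 1000 at 76/1000 for the HIV cohort — realistic
screening-cohort class imbalances) are cleanly separable.

**What passing tests do and do not show.** The generator's language is
a closed vocabulary with clean sentence structure: perfect recovery on
it demonstrates that the annotator implements its own rules exactly and
that the index, profiles and reports preserve those annotations — it
says nothing about recall on real clinical prose, with its typos,
ad-hoc abbreviations, OCR noise, and synonyms outside the dictionary.
Likewise the classifier results show recovery of a known generating
process, not clinical validity.

## Numerical and degenerate-input choices

* Lab-value equality: round both sides to 1 decimal before comparing.
* Classifier: variance floor 1e-6; threshold ties go to the smaller
  threshold; naive-Bayes prediction ties resolve to the alphabetically
  first class; fitting requires ≥ 2 classes, decision tables exactly 2.
* Cross-validation requires every class in every training fold; a class
  thinner than 2 members is rejected up front.
* Empty inputs are valid where they are meaningful: empty note → no
  sentences; no headings → all mentions "unsectioned"; empty cohort →
  empty result; `n_patients=0` → empty corpus and truth.
* Determinism: a single `numpy` Generator seeded from the spec drives
  all generation; all set iterations are sorted before use; JSON output
  uses sorted keys, so identical inputs give byte-identical outputs.

## Known limitations

* No statistical disambiguation, spelling correction or abbreviation
  expansion beyond dictionary synonyms.
* Context assignment is strictly intra-sentential; discourse-level
  negation ("the above were all negative") is out of reach.
* The 8 heading extensions and the automated-profile routing table are
  editable reconstructions, not a published standard.
* The measurement parser handles "alias separator value [unit]" lines
  only — no tables, no intervals ("120-130"), no embedded dates.
* Decision-table classification is binary; multi-class studies must use
  the naive Bayes model.
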