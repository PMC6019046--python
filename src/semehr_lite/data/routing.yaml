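# Automated-profile aspect routing: when a period has no discharge summary,
# mentions are routed to profile aspects by semantic type and context.
# Rules apply in order; the first matching rule wins.
rules:
  - match: {semantic_type: [Pharmacologic Substance, Clinical Drug]}
    route: Admission Medications
  - match:
      semantic_type: [Disease or Syndrome, Sign or Symptom, Finding]
      temporality: [historical]
    route: History of Past Illness
  - match: {experiencer: [other]}
    route: Family History
  - match: {semantic_type: [Individual Behavior]}
    route: Social History
default_route: Other
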