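# Keyword rules for deriving a document type when the note carries none.
# The first 500 characters are scanned case-insensitively; first match wins.
keyword_rules:
  - {keyword: discharge summary, type: Discharge Summary}
  - {keyword: radiology report, type: Radiology}
  - {keyword: radiology, type: Radiology}
  - {keyword: gp letter, type: GP Letter}
  - {keyword: dear dr, type: GP Letter}
  - {keyword: dear doctor, type: GP Letter}
  - {keyword: progress note, type: Progress Note}
  - {keyword: pathology report, type: Pathology}
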