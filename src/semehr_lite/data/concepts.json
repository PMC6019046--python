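[
  {
    "cui": "C0023895",
    "preferred_name": "Liver disease",
    "synonyms": ["liver disease", "liver diseases", "hepatic disease", "disorder of liver"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "235856003", "ICD-10": "K76.9"}
  },
  {
    "cui": "C0019158",
    "preferred_name": "Hepatitis",
    "synonyms": ["hepatitis", "liver inflammation"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "128241005", "ICD-10": "K75.9"}
  },
  {
    "cui": "C0019196",
    "preferred_name": "Hepatitis C",
    "synonyms": ["hepatitis C", "hep C", "HCV infection"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "50711007", "ICD-10": "B18.2"}
  },
  {
    "cui": "C2148557",
    "preferred_name": "Chronic hepatitis C",
    "synonyms": ["chronic hepatitis C", "chronic HCV infection"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "128302006"}
  },
  {
    "cui": "C0220847",
    "preferred_name": "Viral hepatitis C",
    "synonyms": ["viral hepatitis C"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {}
  },
  {
    "cui": "C0151766",
    "preferred_name": "Liver damage",
    "synonyms": ["liver damage"],
    "semantic_type": "Finding",
    "source_codes": {}
  },
  {
    "cui": "C0348754",
    "preferred_name": "Hepatocellular damage",
    "synonyms": ["hepatocellular damage", "hepatocellular injury"],
    "semantic_type": "Finding",
    "source_codes": {}
  },
  {
    "cui": "C2711227",
    "preferred_name": "Steatohepatitis",
    "synonyms": ["steatohepatitis", "fatty liver hepatitis"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {}
  },
  {
    "cui": "C0019699",
    "preferred_name": "HIV Pos",
    "synonyms": ["HIV Pos", "HIV positive", "HIV+"],
    "semantic_type": "Finding",
    "source_codes": {}
  },
  {
    "cui": "C0920550",
    "preferred_name": "HIV diagnosis",
    "synonyms": ["HIV diagnosis", "diagnosis of HIV"],
    "semantic_type": "Finding",
    "source_codes": {}
  },
  {
    "cui": "C0011849",
    "preferred_name": "Diabetes mellitus",
    "synonyms": ["diabetes", "diabetes mellitus"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "73211009", "ICD-10": "E14"}
  },
  {
    "cui": "C0020538",
    "preferred_name": "Hypertension",
    "synonyms": ["hypertension", "high blood pressure", "htn"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "38341003", "ICD-10": "I10"}
  },
  {
    "cui": "C0004096",
    "preferred_name": "Asthma",
    "synonyms": ["asthma"],
    "semantic_type": "Disease or Syndrome",
    "source_codes": {"SNOMED CT": "195967001", "ICD-10": "J45"}
  },
  {
    "cui": "C0010200",
    "preferred_name": "Cough",
    "synonyms": ["cough", "coughing"],
    "semantic_type": "Sign or Symptom",
    "source_codes": {"SNOMED CT": "49727002"}
  },
  {
    "cui": "C0015967",
    "preferred_name": "Fever",
    "synonyms": ["fever", "pyrexia", "febrile illness"],
    "semantic_type": "Sign or Symptom",
    "source_codes": {"SNOMED CT": "386661006"}
  },
  {
    "cui": "C0018681",
    "preferred_name": "Headache",
    "synonyms": ["headache", "cephalgia"],
    "semantic_type": "Sign or Symptom",
    "source_codes": {"SNOMED CT": "25064002"}
  },
  {
    "cui": "C0008031",
    "preferred_name": "Chest pain",
    "synonyms": ["chest pain"],
    "semantic_type": "Sign or Symptom",
    "source_codes": {"SNOMED CT": "29857009"}
  },
  {
    "cui": "C0013404",
    "preferred_name": "Dyspnea",
    "synonyms": ["dyspnea", "shortness of breath", "breathlessness"],
    "semantic_type": "Sign or Symptom",
    "source_codes": {"SNOMED CT": "267036007"}
  },
  {
    "cui": "C0035525",
    "preferred_name": "Ribavirin",
    "synonyms": ["ribavirin"],
    "semantic_type": "Pharmacologic Substance",
    "source_codes": {}
  },
  {
    "cui": "C0004057",
    "preferred_name": "Aspirin",
    "synonyms": ["aspirin", "acetylsalicylic acid"],
    "semantic_type": "Pharmacologic Substance",
    "source_codes": {}
  },
  {
    "cui": "C0025598",
    "preferred_name": "Metformin",
    "synonyms": ["metformin"],
    "semantic_type": "Pharmacologic Substance",
    "source_codes": {}
  },
  {
    "cui": "C0037369",
    "preferred_name": "Smoking",
    "synonyms": ["smoking", "smoker", "tobacco use"],
    "semantic_type": "Individual Behavior",
    "source_codes": {}
  },
  {
    "cui": "C0001948",
    "preferred_name": "Alcohol consumption",
    "synonyms": ["alcohol use", "drinks alcohol", "alcohol intake"],
    "semantic_type": "Individual Behavior",
    "source_codes": {}
  }
]
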