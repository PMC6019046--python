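# Measurement extraction rule table: one row per laboratory measurement.
# name_umls is the canonical (UMLS-style) label, name_source the label the
# source system uses in notes and in the structured lab-events table.
# Values parsed outside [lo, hi] are dropped as implausible.
measurements:
  - name_umls: Hematocrit
    name_source: Hematocrit
    aliases: [hematocrit, hct]
    unit: "%"
    plausible_range: [15.0, 65.0]
  - name_umls: Platelets
    name_source: Platelet count
    aliases: [platelet count, platelets, plt]
    unit: K/uL
    plausible_range: [10.0, 1000.0]
  - name_umls: Sodium
    name_source: Sodium
    aliases: [sodium, na]
    unit: mEq/L
    plausible_range: [110.0, 165.0]
  - name_umls: Mean corpuscular hemoglobin concentration
    name_source: Mean corpuscular hemoglobin concentration
    aliases: [mean corpuscular hemoglobin concentration, mchc]
    unit: "%"
    plausible_range: [25.0, 40.0]
  - name_umls: Alanine aminotransferase
    name_source: Alanine aminotransferase
    aliases: [alanine aminotransferase, alt]
    unit: IU/L
    plausible_range: [5.0, 5000.0]
  - name_umls: Red blood cell distribution width
    name_source: Red blood cell distribution width
    aliases: [red blood cell distribution width, red cell distribution width, rdw]
    unit: "%"
    plausible_range: [10.0, 35.0]
  - name_umls: Serum aspartate aminotransferase
    name_source: Aspartate aminotransferase
    aliases: [aspartate aminotransferase, ast]
    unit: IU/L
    plausible_range: [5.0, 5000.0]
  - name_umls: Chloride
    name_source: Chloride
    aliases: [chloride, cl]
    unit: mEq/L
    plausible_range: [80.0, 130.0]
  - name_umls: Blood urea
    name_source: Urea nitrogen
    aliases: [urea nitrogen, blood urea nitrogen, bun]
    unit: mg/dL
    plausible_range: [2.0, 200.0]
  - name_umls: Leukocytes
    name_source: White blood cells
    aliases: [white blood cells, white blood cell count, white count, wbc]
    unit: K/uL
    plausible_range: [0.5, 120.0]
  - name_umls: Glucose
    name_source: Glucose
    aliases: [glucose, blood glucose]
    unit: mg/dL
    plausible_range: [30.0, 1000.0]
# Sections scanned for measurement lines (canonical labels); "Other"
# catches unmapped lab-like headings.
scan_sections:
  - Hospital Discharge Physical
  - Laboratory Results
  - Vital Signs
  - Other
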