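# Canonical section set for discharge-summary structuring:
# 23 labels from the FHIR CCDA discharge-summary composition plus 8
# extensions (the extension list is a configurable stand-in; edit freely).
# Each canonical label maps to the normalized heading aliases that resolve
# to it.  The label itself always matches, so aliases list only variants.
fhir_labels:
  Allergies and Intolerances:
    - allergies
    - allergy
    - adverse reactions
  Chief Complaint:
    - cc
    - presenting complaint
  Chief Complaint and Reason for Visit:
    - chief complaint and reason for visit
  Discharge Diet:
    - diet
    - diet at discharge
  Family History:
    - family hx
    - fh
    - fhx
  Functional Status:
    - functional state
  History of Past Illness:
    - past medical history
    - pmh
    - pmhx
    - past history
  History of Present Illness:
    - hpi
    - present illness
  Hospital Consultations:
    - consultations
    - consults
  Hospital Course:
    - course
    - brief hospital course
  Hospital Discharge Instructions:
    - discharge instructions
    - instructions
  Hospital Discharge Medications:
    - discharge medications
    - medications on discharge
    - discharge meds
  Hospital Discharge Physical:
    - discharge physical
    - discharge exam
    - physical exam at discharge
  Hospital Discharge Studies Summary:
    - discharge studies
    - studies summary
  Immunizations:
    - immunisations
    - vaccinations
  Admission Medications:
    - medications on admission
    - meds on admission
    - admission meds
  Problem:
    - problems
    - problem list
  Procedures:
    - procedures performed
    - operations
  Reason for Visit:
    - reason for admission
  Review of Systems:
    - ros
    - systems review
  Social History:
    - social hx
    - sh
    - shx
  Vital Signs:
    - vitals
  Plan of Treatment:
    - plan
    - treatment plan
extension_labels:
  Laboratory Results:
    - labs
    - lab results
    - laboratory data
  Admission Diagnosis:
    - diagnosis on admission
  Discharge Diagnosis:
    - final diagnosis
    - diagnosis at discharge
  Past Surgical History:
    - psh
    - surgical history
  Physical Examination:
    - physical exam
    - examination
    - exam
  Assessment and Plan:
    - assessment
    - impression and plan
  Impression:
    - radiology impression
  Follow-Up:
    - follow up
    - followup arrangements
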