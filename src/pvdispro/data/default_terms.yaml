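# Default preferred-term → disease-category dictionary.
#
# This is a small, documented stand-in mapping of common rheumatoid-arthritis
# pharmacovigilance preferred terms to the six disease categories analysed by
# the pipeline.  It is NOT an official MedDRA grouping: any real analysis must
# supply its own dictionary as explicit configuration.  Matching is exact and
# case-insensitive on the preferred-term string; "arthralgia" is kept as its
# own single-term category, disjoint from the broader musculoskeletal set.
cardiovascular:
  - myocardial infarction
  - acute myocardial infarction
  - cardiac failure
  - cardiac failure congestive
  - atrial fibrillation
  - cerebrovascular accident
  - deep vein thrombosis
  - pulmonary embolism
  - hypertension
  - pericarditis
  - angina pectoris
  - tachycardia
  - palpitations
  - cardiac arrest
  - thrombosis
cancer:
  - malignant neoplasm
  - lung neoplasm malignant
  - breast cancer
  - lymphoma
  - non-hodgkin's lymphoma
  - leukaemia
  - melanoma
  - basal cell carcinoma
  - squamous cell carcinoma
  - prostate cancer
  - colon cancer
  - neoplasm malignant
  - metastases to liver
  - skin cancer
respiratory:
  - pneumonia
  - dyspnoea
  - cough
  - upper respiratory tract infection
  - bronchitis
  - chronic obstructive pulmonary disease
  - interstitial lung disease
  - respiratory failure
  - pleural effusion
  - asthma
  - sinusitis
  - nasopharyngitis
  - pulmonary fibrosis
gastrointestinal:
  - nausea
  - vomiting
  - diarrhoea
  - abdominal pain
  - abdominal pain upper
  - constipation
  - gastrointestinal haemorrhage
  - gastrointestinal perforation
  - dyspepsia
  - gastritis
  - pancreatitis
  - diverticulitis
  - colitis
musculoskeletal:
  - pain in extremity
  - back pain
  - myalgia
  - muscle spasms
  - musculoskeletal pain
  - musculoskeletal stiffness
  - osteoarthritis
  - osteoporosis
  - bone pain
  - joint swelling
  - joint stiffness
  - neck pain
  - rheumatoid arthritis
  - tendonitis
  - fracture
arthralgia:
  - arthralgia
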