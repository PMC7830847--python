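# Abstract procedure/drug code vocabulary.
#
# Real regional billing systems (ICD-9-CM procedure codes, ambulatory care
# nomenclature, ATC) are proprietary to the data owner, so the engine works
# against named tokens; deploying on real data only requires remapping each
# token to the local code list in this file.
codes:
  CT_THORAX:        {tables: [outpatient], description: thorax computed tomography}
  CT_ABDOMEN:       {tables: [outpatient], description: abdominal computed tomography}
  US_ABDOMEN:       {tables: [outpatient], description: abdominal ultrasound}
  CT_HEAD:          {tables: [outpatient], description: head computed tomography}
  MR_HEAD:          {tables: [outpatient], description: head magnetic resonance}
  PET:              {tables: [outpatient], description: positron emission tomography}
  BONE_SCAN:        {tables: [outpatient], description: bone scintigraphy}
  BRONCHOSCOPY:     {tables: [outpatient], description: bronchoscopy with sampling}
  NEEDLE_BIOPSY:    {tables: [outpatient], description: percutaneous/transthoracic biopsy}
  WEDGE_RESECTION:  {tables: [inpatient], description: atypical (wedge) lung resection}
  SEGMENTECTOMY:    {tables: [inpatient], description: anatomical segmentectomy}
  LOBECTOMY:        {tables: [inpatient], description: lobectomy}
  PNEUMONECTOMY:    {tables: [inpatient], description: pneumonectomy}
  CHEMO:            {tables: [outpatient, inpatient], description: antineoplastic drug administration}
  RT_FRACTION:      {tables: [outpatient], description: radiotherapy fraction}
  MDT_EVAL:         {tables: [outpatient], description: multidisciplinary team evaluation}
  LUNG_FUNCTION:    {tables: [outpatient], description: pre-operative lung function testing}
  PALLIATIVE_CARE:  {tables: [inpatient], description: palliative/hospice/home-care admission}
  OPIOID_ATC:       {tables: [prescriptions], description: opioid analgesic dispensation}
  FOLLOWUP_VISIT:   {tables: [outpatient], description: oncological follow-up visit}
  PLANNED_ADMISSION: {tables: [inpatient], description: planned (non-urgent) hospital admission}
  EMERGENCY_ACCESS: {tables: [emergency], description: emergency department access}
  GP_VISIT:         {tables: [outpatient], description: generic ambulatory contact}

groups:
  lung_surgery: [WEDGE_RESECTION, SEGMENTECTOMY, LOBECTOMY, PNEUMONECTOMY]
  curative_surgery: [SEGMENTECTOMY, LOBECTOMY, PNEUMONECTOMY]
  biopsy: [BRONCHOSCOPY, NEEDLE_BIOPSY]
  head_imaging: [CT_HEAD, MR_HEAD]
  metastasis_imaging: [PET, BONE_SCAN]
  abdominal_imaging: [CT_ABDOMEN, US_ABDOMEN]
  chemo: [CHEMO]
  radiotherapy: [RT_FRACTION]
  opioid: [OPIOID_ATC]
  followup: [FOLLOWUP_VISIT, PLANNED_ADMISSION]

# Comorbidity coding for the registry-linkage Charlson adaptation: 12-month
# pre-incidence lookback over inpatient + outpatient codes, one token per
# condition, standard condition weights.  Malignancy categories are excluded
# (the index cancer would otherwise score every patient).
charlson:
  CM_MI:              {condition: myocardial infarction, weight: 1}
  CM_CHF:             {condition: congestive heart failure, weight: 1}
  CM_PVD:             {condition: peripheral vascular disease, weight: 1}
  CM_CVD:             {condition: cerebrovascular disease, weight: 1}
  CM_DEMENTIA:        {condition: dementia, weight: 1}
  CM_COPD:            {condition: chronic pulmonary disease, weight: 1}
  CM_RHEUM:           {condition: rheumatologic disease, weight: 1}
  CM_PUD:             {condition: peptic ulcer disease, weight: 1}
  CM_LIVER_MILD:      {condition: mild liver disease, weight: 1}
  CM_DIABETES:        {condition: diabetes, weight: 1}
  CM_DIABETES_COMPL:  {condition: diabetes with complications, weight: 2}
  CM_HEMIPLEGIA:      {condition: hemiplegia, weight: 2}
  CM_RENAL:           {condition: renal disease, weight: 2}
  CM_LIVER_SEVERE:    {condition: moderate or severe liver disease, weight: 3}
  CM_AIDS:            {condition: AIDS, weight: 6}
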