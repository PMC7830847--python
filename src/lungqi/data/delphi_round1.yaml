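# Round-1 consensus-survey conditions for the synthetic expert panel.
#
# 34 candidate indicators entered the scored web survey; the 21 that passed
# are the final catalog minus O4 (O4 was proposed by the panel during the
# round and never scored).  The 13 rejected candidates are plausible
# guideline-derived measures that failed at least one retention criterion;
# per-candidate fractions below are the share of complete responders scoring
# validity >=5 and modifiability/utility >=4, and drive the quota-based
# synthetic score generator.
invited: 225
responded: 95
completed_full: 85
# respondents completing each questionnaire section
section_respondents:
  organization: 95
  diagnosis: 92
  surgery: 90
  medical: 87
  followup: 85
candidates:
  - {id: O1, section: organization, pass: true,  frac_validity: 0.88, frac_mod: 0.55, frac_util: 0.80}
  - {id: O2, section: organization, pass: true,  frac_validity: 0.85, frac_mod: 0.55, frac_util: 0.75}
  - {id: O3, section: organization, pass: true,  frac_validity: 0.90, frac_mod: 0.65, frac_util: 0.85}
  - {id: D1, section: diagnosis,    pass: true,  frac_validity: 0.85, frac_mod: 0.52, frac_util: 0.70}
  - {id: D2, section: diagnosis,    pass: true,  frac_validity: 0.86, frac_mod: 0.58, frac_util: 0.78}
  - {id: D3, section: diagnosis,    pass: true,  frac_validity: 0.87, frac_mod: 0.55, frac_util: 0.78}
  - {id: D4, section: diagnosis,    pass: true,  frac_validity: 0.92, frac_mod: 0.55, frac_util: 0.82}
  - {id: D5, section: diagnosis,    pass: true,  frac_validity: 0.86, frac_mod: 0.60, frac_util: 0.78}
  - {id: D6, section: diagnosis,    pass: true,  frac_validity: 0.87, frac_mod: 0.60, frac_util: 0.80}
  - {id: S1, section: surgery,      pass: true,  frac_validity: 0.93, frac_mod: 0.55, frac_util: 0.82}
  - {id: S2, section: surgery,      pass: true,  frac_validity: 0.86, frac_mod: 0.55, frac_util: 0.80}
  - {id: S3, section: surgery,      pass: true,  frac_validity: 0.95, frac_mod: 0.62, frac_util: 0.82}
  - {id: S4, section: surgery,      pass: true,  frac_validity: 0.88, frac_mod: 0.62, frac_util: 0.80}
  - {id: S5, section: surgery,      pass: true,  frac_validity: 0.86, frac_mod: 0.55, frac_util: 0.76}
  - {id: S6, section: surgery,      pass: true,  frac_validity: 0.92, frac_mod: 0.52, frac_util: 0.80}
  - {id: S7, section: surgery,      pass: true,  frac_validity: 0.86, frac_mod: 0.56, frac_util: 0.80}
  - {id: M1, section: medical,      pass: true,  frac_validity: 0.80, frac_mod: 0.55, frac_util: 0.70}
  - {id: M2, section: medical,      pass: true,  frac_validity: 0.85, frac_mod: 0.55, frac_util: 0.72}
  - {id: M3, section: medical,      pass: true,  frac_validity: 0.90, frac_mod: 0.62, frac_util: 0.82}
  - {id: M4, section: medical,      pass: true,  frac_validity: 0.88, frac_mod: 0.62, frac_util: 0.78}
  - {id: F1, section: followup,     pass: true,  frac_validity: 0.86, frac_mod: 0.60, frac_util: 0.80}
  - {id: X01, name: "Smoking cessation support documented at diagnosis",        section: organization, pass: false, frac_validity: 0.55, frac_mod: 0.60, frac_util: 0.65}
  - {id: X02, name: "Time from referral to first specialist visit <=14 days",   section: organization, pass: false, frac_validity: 0.70, frac_mod: 0.40, frac_util: 0.60}
  - {id: X03, name: "Brain MRI for all stage I-II NSCLC before surgery",        section: diagnosis,    pass: false, frac_validity: 0.50, frac_mod: 0.55, frac_util: 0.55}
  - {id: X04, name: "Mediastinoscopy before resection in cN2 disease",          section: diagnosis,    pass: false, frac_validity: 0.68, frac_mod: 0.45, frac_util: 0.45}
  - {id: X05, name: "Molecular testing for advanced non-squamous NSCLC",        section: diagnosis,    pass: false, frac_validity: 0.72, frac_mod: 0.42, frac_util: 0.48}
  - {id: X06, name: "Repeat cytology when first sample inadequate",             section: diagnosis,    pass: false, frac_validity: 0.60, frac_mod: 0.55, frac_util: 0.58}
  - {id: X07, name: "Thoracoscore documented before resection",                 section: surgery,      pass: false, frac_validity: 0.45, frac_mod: 0.50, frac_util: 0.52}
  - {id: X08, name: "Nodal sampling of >=6 stations at resection",              section: surgery,      pass: false, frac_validity: 0.73, frac_mod: 0.48, frac_util: 0.44}
  - {id: X09, name: "Re-admission to intensive care after lung resection",      section: surgery,      pass: false, frac_validity: 0.58, frac_mod: 0.35, frac_util: 0.55}
  - {id: X10, name: "Adjuvant chemotherapy within 8 weeks of resection",        section: medical,      pass: false, frac_validity: 0.71, frac_mod: 0.46, frac_util: 0.60}
  - {id: X11, name: "Erythropoietin avoided during curative chemo-radiation",   section: medical,      pass: false, frac_validity: 0.52, frac_mod: 0.55, frac_util: 0.50}
  - {id: X12, name: "Second-line therapy offered after progression",            section: medical,      pass: false, frac_validity: 0.65, frac_mod: 0.42, frac_util: 0.62}
  - {id: X13, name: "CT surveillance intensity per protocol in follow-up",      section: followup,     pass: false, frac_validity: 0.62, frac_mod: 0.52, frac_util: 0.44}

# Published round-1 score summaries (median and quartiles) of the retained
# indicators, shipped for the feedback report; O4 was never scored.
table1_scores:
  O1: {n: 95, validity: [5, 6, 6],   modifiability: [3, 4, 5],   utility: [5, 6, 6]}
  O2: {n: 95, validity: [5, 6, 7],   modifiability: [3, 4, 5],   utility: [4, 5, 6]}
  O3: {n: 95, validity: [5, 6, 7],   modifiability: [4, 5, 6],   utility: [5, 6, 7]}
  D1: {n: 92, validity: [5, 6, 7],   modifiability: [2, 4, 6],   utility: [3, 5, 6.5]}
  D2: {n: 92, validity: [5, 6, 7],   modifiability: [3, 4.5, 6], utility: [4, 6, 7]}
  D3: {n: 92, validity: [5, 6, 7],   modifiability: [3, 4, 6],   utility: [4, 6, 7]}
  D4: {n: 92, validity: [5, 6.5, 7], modifiability: [3, 4, 6],   utility: [5, 6, 7]}
  D5: {n: 92, validity: [5, 6, 7],   modifiability: [3, 5, 6],   utility: [4, 6, 7]}
  D6: {n: 92, validity: [5, 6, 7],   modifiability: [3, 5, 6],   utility: [5, 6, 7]}
  S1: {n: 90, validity: [6, 6, 7],   modifiability: [2, 4.5, 6], utility: [5, 6, 7]}
  S2: {n: 90, validity: [5, 6, 7],   modifiability: [3, 4, 6],   utility: [5, 6, 7]}
  S3: {n: 90, validity: [6, 7, 7],   modifiability: [3, 5, 6],   utility: [5, 6, 7]}
  S4: {n: 90, validity: [5, 6, 7],   modifiability: [3, 5, 6],   utility: [5, 6, 7]}
  S5: {n: 90, validity: [5, 6, 7],   modifiability: [3, 4, 6],   utility: [5, 6, 6]}
  S6: {n: 90, validity: [6, 6, 7],   modifiability: [2, 4, 6],   utility: [5, 6, 7]}
  S7: {n: 90, validity: [5, 6, 7],   modifiability: [3, 4, 6],   utility: [5, 6, 7]}
  M1: {n: 87, validity: [5, 5, 6],   modifiability: [3, 4, 5],   utility: [4, 5, 6]}
  M2: {n: 87, validity: [5, 6, 7],   modifiability: [3, 4, 5],   utility: [4, 5, 6]}
  M3: {n: 85, validity: [6, 6, 7],   modifiability: [3, 5, 6],   utility: [5, 6, 7]}
  M4: {n: 85, validity: [5, 6, 7],   modifiability: [3, 5, 6],   utility: [4, 6, 7]}
  F1: {n: 85, validity: [5, 6, 7],   modifiability: [3, 5, 6],   utility: [5, 6, 7]}
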