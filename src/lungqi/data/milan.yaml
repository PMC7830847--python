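# Default study conditions: the published marginals of the 2007-2012 Milan
# province lung-cancer cohort and the published per-indicator counts used to
# calibrate the synthetic linked databases.  These printed counts are inputs
# to the generator, not outputs of this package.
cohort:
  n_patients: 5860           # raw registry rows, before exclusions
  dco_count: 88
  mesenchymal_count: 26
  years: [2007, 2012]
  censor_date: "2016-12-31"
  epoch: "2006-01-01"
  n_providers: 92
  tau2: 0.3                  # provider random-intercept variance, log-odds scale
  male_count: 4310
  year_counts: {2007: 909, 2008: 952, 2009: 1015, 2010: 975, 2011: 945, 2012: 950}
  age_class_counts:
    "<=55": 422
    "56-60": 496
    "61-65": 797
    "66-70": 1010
    "71-75": 1163
    "76-80": 1002
    ">80": 856
  charlson_counts: {"0": 3256, "1": 1226, "2": 627, ">=3": 334}
  stage_counts: {missing: 879, I: 611, II: 526, III: 1068, IV: 2662}
  confirmed_count: 4814
  sclc_count: 510
  treatment_counts:
    none: 2350
    surgery: 1124
    chemoradiation: 388
    chemotherapy: 1570
    radiotherapy: 314
  deceased_by_censor: 4798
  alive_after_years: {2: 1552, 3: 1169, 4: 892}

# Published overall numerator/denominator pairs of the pilot calculation.
indicator_targets:
  O1:  [1750, 2663]
  O2:  [518, 706]
  O4:  [491, 759]
  D1:  [4416, 5746]
  D2:  [2487, 3283]
  D3:  [1098, 2125]
  D4:  [4814, 5746]
  D5:  [166, 403]
  D6:  [50, 510]
  S1:  [1115, 1124]
  S2:  [330, 1124]
  S4:  [897, 1768]
  S5:  [687, 1005]
  S6:  [1117, 1124]
  S7:  [611, 930]
  M1:  [46, 977]
  M2:  [143, 234]
  M4:  [4414, 4798]
  F1y2: [1122, 1552]
  F1y3: [861, 1169]
  F1y4: [715, 892]

# Published chart-review agreement counts: [discordant, evaluated] per
# indicator, over the stratified validation subsample of 114 patients.
# Discordant = procedure in the chart, code absent from the databases.
chart_review:
  sample_size: 114
  O1: [17, 97]
  O2: [1, 16]
  O4: [1, 16]
  D1: [12, 114]
  D2: [15, 79]
  D3: [10, 38]
  D4: [0, 114]
  D5: [4, 22]
  D6: [18, 28]
  S1: [0, 25]
  S2: [6, 25]
  S4: [0, 56]
  S5: [0, 24]
  S6: [0, 25]
  S7: [0, 20]
  M1: [0, 40]
  M2: [0, 21]
  M4: [1, 90]

delphi:
  invited: 225
  responded: 95
  completed_full: 85
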