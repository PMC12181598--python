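# Synthetic demo configuration: a self-contained run on simulated data that
# emulates the reference study design (24 old females, 28 old males, 13+13
# young references, three timed function tests, five serum markers planted
# with sex-specific effects).  All inputs are generated; nothing here is
# measured data.
seed: 0
k: 40
score_mode: min
sexes: [F, M]
tests: [walk400, gait4, chair5]
term_ids: all

simulate:
  n_old_female: 24
  n_old_male: 28
  n_young_female: 13
  n_young_male: 13
  n_genes: 2000
  walk_cap_seconds: 900
  test_correlation: 0.6
  planted_markers:
    # sex-specific gene-phenotype correlations of study-like magnitude
    - {gene_id: MSTN,   sex: F, test: gait4,   target_r: 0.53}
    - {gene_id: LGALS1, sex: F, test: chair5,  target_r: 0.71}
    - {gene_id: CTSB,   sex: M, test: walk400, target_r: -0.54}
    - {gene_id: THBS4,  sex: M, test: gait4,   target_r: -0.48}
    - {gene_id: TTN,    sex: M, test: walk400, target_r: -0.51}
  serum_markers:
    # shift per fitness tertile (SD units, positive = higher when slower)
    # and old-vs-young shift
    - {marker_name: MSTN,   sex_effect: F,    standardized_shift_per_tertile: 0.9,  old_young_shift: -0.6}
    - {marker_name: LGALS1, sex_effect: F,    standardized_shift_per_tertile: 1.0,  old_young_shift: 0.4}
    - {marker_name: CTSB,   sex_effect: M,    standardized_shift_per_tertile: -1.0, old_young_shift: 0.6}
    - {marker_name: THBS4,  sex_effect: M,    standardized_shift_per_tertile: -0.9, old_young_shift: 0.5}
    - {marker_name: TTN,    sex_effect: none, standardized_shift_per_tertile: 0.0,  old_young_shift: 0.5}
  kb_composition:
    mean_records_per_gene: 2.0
    force_qualify: [MSTN, LGALS1, CTSB, THBS4, TTN]

validate:
  markers:
    MSTN:   {test: gait4,   direction: greater}
    LGALS1: {test: chair5,  direction: greater}
    CTSB:   {test: walk400, direction: less}
    THBS4:  {test: gait4,   direction: less}
    TTN:    {test: walk400, direction: less}

predict:
  F:
    tests: [gait4, chair5]
    panels:
      age_bmi: [age, bmi]
      matched_markers: [MSTN, LGALS1]
      cross_markers: [CTSB, THBS4]
      matched_plus_age_bmi: [MSTN, LGALS1, age, bmi]
  M:
    tests: [gait4, walk400]
    panels:
      age_bmi: [age, bmi]
      matched_markers: [CTSB, THBS4]
      cross_markers: [MSTN, LGALS1]
      matched_plus_age_bmi: [CTSB, THBS4, age, bmi]
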