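# Example generator configuration approximating the packaged audit's
# marginal frequencies (16 studies; publications and websites always
# findable, registries ~11/16, data documents ~10/16; design mix dominated
# by full three-route ascertainment; infrastructure ~11/16 split 7:3:1).
seed: 0
n_studies: 16
p_source_present:
  scientific_publications: 1.0
  study_website: 1.0
  study_trial_registries: 0.6875
  data_documents: 0.625
default_coverage:
  complete: 0.5
  partial: 0.2
  absent: 0.3
p_indirect_upgrade: 0.5
quality_sd: 0.0
design_mix:
  full: 0.6875
  no_admin: 0.1875
  no_exams: 0.0625
  survey_only: 0.0625
p_infrastructure_available: 0.6875
accessibility_mix: [7, 3, 1]
survey:
  n_respondents: 10
  default_p_yes: 0.6
  barrier_levels:
    limited_financial: [0.6, 0.3, 0.1]
    limited_human: [0.8, 0.1, 0.1]
    limited_technical: [0.5, 0.3, 0.2]
    limited_incentives: [0.4, 0.4, 0.2]
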