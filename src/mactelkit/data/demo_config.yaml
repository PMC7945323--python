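# Demo pipeline configuration: a small synthetic cohort that exercises
# every stage in under a minute.  Thresholds carry the conventional
# values (genome-wide 5e-8, FDR 0.05); cohort sizes are scaled down from
# the reference architecture (2209 subjects, 476 cases) for speed.
seed: 0

cohort:
  n_subjects: 1200
  n_cases_target: 260
  n_snps: 60
  disease_prevalence: 0.1
  n_patients_retina: 60
  n_phenotypes: 36
  n_factors: 4
  n_visits_mean: 3.0
  retina_missing_fraction: 0.05

mr:
  alpha: 0.05
  quintile_trait: serine
  quintile_contrast: [0, 4]

scan:
  threshold: 5.0e-8
  condition_on: [serine, glycine]
  interaction_with: serine
  window_bp: 1000000

retina:
  effect_trait: serine
  effect_size: 0.4
  # lead SNPs from the conditional scan are added automatically; these
  # two (a serine instrument and a T2D instrument) guarantee a
  # multi-predictor clustering stage even when the small demo scan
  # calls no genome-wide peaks
  predictor_snps: [rs10001, rs10170]
  n_lead_snps: 3
  max_missing_fraction: 0.2
  n_factors_fit: 4

endo_assoc:
  n_endophenotypes_tested: 4
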