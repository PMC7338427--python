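# Cohort preset: healthy sex/age-matched control arm.
# Medians transcribed from the published cohort results.  The six printed
# CD4 maturation medians sum to 100.3% (> 100, as cohort medians may); they
# are rescaled by 99.5/100.3 so per-subject compositions remain a simplex,
# reserving 0.5% for the unnamed CD27-CCR7+ phenotypes.
name: control
n_subjects: 46
median_lymph_abs: 2676.0
median_lymph_pct: 46.8
dispersion: 0.25
subset_median_pct:
  T: 72.9
  B: 14.1
  NK: 9.7
  CD4: 59.122      # printed 43.1% of lymphocytes / T 72.9
  CD8: 31.276      # printed 22.8% of lymphocytes / T 72.9
  RTE_CD4: 48.9
  RTE_CD8: 59.4
  TN_CD4: 67.061   # printed 67.6, rescaled (see header)
  TCM_CD4: 16.666  # printed 16.8
  TEM_CD4: 10.416  # printed 10.5
  LTEMRA_CD4: 1.786   # printed 1.8
  HTEMRA_CD4: 0.397   # printed 0.4
  TD_CD4: 3.174    # printed 3.2
  TN_CD8: 48.6
  TCM_CD8: 2.8
  TEM_CD8: 17.1
  LTEMRA_CD8: 13.9
  HTEMRA_CD8: 6.3
  TD_CD8: 3.5
  TSCM_CD4: 1.8
  TEMRA_CD4: 0.1
  TSCM_CD8: 6.6
  TEMRA_CD8: 3.2
  CD57_CD4: 0.5
  KLRG1_CD4: 7.2
  PD1_CD4: 2.6
  CD57_CD8: 9.6
  KLRG1_CD8: 44.4
  PD1_CD8: 3.3
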