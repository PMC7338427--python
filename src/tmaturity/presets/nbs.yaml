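# Cohort preset: NBS (Nijmegen Breakage Syndrome) study arm.
# Medians transcribed from the published cohort results.  CD4/CD8 are
# re-parameterised as % of T (printed as % of lymphocytes: CD4 25.9, CD8
# 16.7, T 52.7); maturation subsets are % of their CD4/CD8 parent.
name: nbs
n_subjects: 46
median_lymph_abs: 1330.0      # cells/ul
median_lymph_pct: 27.2        # % of leukocyte-like events
dispersion: 0.25              # shared logit/log-scale sd
subset_median_pct:
  T: 52.7
  B: 8.7
  NK: 32.3
  CD4: 49.146
  CD8: 31.689
  RTE_CD4: 6.6
  RTE_CD8: 32.7
  TN_CD4: 11.6
  TCM_CD4: 28.6
  TEM_CD4: 24.4
  LTEMRA_CD4: 1.7
  HTEMRA_CD4: 1.2
  TD_CD4: 13.0
  TN_CD8: 13.7
  TCM_CD8: 4.3
  TEM_CD8: 18.9
  LTEMRA_CD8: 9.1
  HTEMRA_CD8: 20.6
  TD_CD8: 7.4
  TSCM_CD4: 2.1
  TEMRA_CD4: 0.7
  TSCM_CD8: 6.8
  TEMRA_CD8: 6.8
  CD57_CD4: 5.9
  KLRG1_CD4: 46.0
  PD1_CD4: 10.7
  CD57_CD8: 25.2
  KLRG1_CD8: 88.0
  PD1_CD8: 7.3
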