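# Versioned calibration constants for the synthetic cohort and rater-table
# generators.  Single source of truth used by the default generators, the
# acceptance report and the tests.
#
# Cohort volume marginals are log-normal, parameterized by the published
# median and interquartile range of the ICV-corrected volumes (mm^3 cm^-3).
# Age dependence is a Gaussian copula at the published Spearman level.
# Rater variance components live on the Ln(x+1) scale; the population
# ICC(2,1) implied by each triple equals the published estimate.
version: 1
cohort:
  n: 98
  age_range: [14.0, 84.0]
  male_fraction: 0.45918367346938777   # 45 of 98
  dv:
    corrected_median: 0.102
    corrected_iqr: [0.037, 0.324]
    age_spearman: -0.330
    male_female_ratio: 2.0
  psd:
    corrected_median: 0.482
    corrected_iqr: [0.239, 0.987]
    age_spearman: 0.385
    male_female_ratio: 1.7
  dv_psd_spearman: 0.0
  icv:
    median_cm3: 1500.0
    sigma_log: 0.08
    male_female_ratio: 1.12
raters:
  n_subjects: 10
  dv:
    icc: 0.971
    mean_log: 5.069      # Ln(158.057 + 1)
    subject_var: 1.44
    rater_var: 0.0086
    residual_var: 0.0344
  psd:
    icc: 0.997
    mean_log: 6.490      # Ln(657.593 + 1)
    subject_var: 1.0
    rater_var: 0.000602
    residual_var: 0.002407
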