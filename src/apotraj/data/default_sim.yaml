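# Default calibration of the synthetic primary-care-EHR cohort.
#
# Covariate marginals and woman-level adverse-pregnancy-outcome (APO)
# prevalence targets reproduce the published cohort description of a UK
# primary-care pregnancy cohort (mean age at first pregnancy 27.1 y,
# gestational hypertension 9.4%, APO-count distribution 71.7/21.2/5.7/1.5 %,
# median 6 BP measurements per woman).  True mean systolic-BP curves by
# APO-count group interpolate the published predicted values at 10 years
# before and 10 years after first pregnancy.  All other numbers are
# package-chosen plumbing (documented in docs/methods.md).

cohort:
  # fraction of women with hospital-episode linkage; preterm-birth and
  # SGA/LGA flags are underivable (missing) without it
  hes_linkage_rate: 0.545

covariates:
  age_first_pregnancy: {mean: 27.1, sd: 6.6, min: 12.0, max: 55.0}
  # quintile probabilities 1 (least deprived) .. 5 (most deprived) plus a
  # small missing fraction; renormalised at load time
  townsend_quintile:
    probs: [0.212, 0.204, 0.209, 0.216, 0.160]
    missing: 0.0011
  ethnicity: {white: 0.865, non_white: 0.102, unknown: 0.033}
  smoking_ever: 0.45
  parity:
    probs: {1: 0.416, 2: 0.281, 3: 0.150, 4: 0.080, 5: 0.045, 6: 0.0172, 7: 0.0063, 8: 0.0035}
  ever_nonsingleton: 0.011
  med_antihypertensive: 0.059
  med_lipid_lowering: 0.003
  med_hypoglycaemic: 0.010

apo:
  # woman-level any-pregnancy prevalence targets; ptb/sga/lga are targets
  # among HES-linked women
  prevalence:
    gestational_hypertension: 0.094
    preeclampsia: 0.040
    gestational_diabetes: 0.040
    ptb_spontaneous: 0.056
    ptb_indicated: 0.031
    sga: 0.124
    lga: 0.117
    stillbirth: 0.007
  miscarriage:
    any: 0.186
    multiple: 0.006   # 3+ miscarriages across pregnancies
  # frailty loadings on the shared latent woman-level risk factor;
  # calibrated once (deterministic quadrature model, least squares against
  # the APO-count distribution) and frozen here
  loadings:
    hypertensive_metabolic: 0.2169   # gestational hypertension, PE, GD
    birth_outcome: 2.7438            # PTB, SGA, LGA, stillbirth
  # reference APO-count distribution (0 / 1 / 2 / 3+) the loadings were
  # calibrated against
  count_targets: [0.7174, 0.2116, 0.0565, 0.0145]
  congenital_anomaly: 0.031

pregnancy_timing:
  gestation_birth: 0.75        # years, live birth / stillbirth
  gestation_miscarriage: 0.30  # years
  gap_min: 1.0                 # uniform inter-pregnancy gap, years
  gap_max: 4.0

observation:
  window: [-10.0, 15.0]   # years relative to first pregnancy start
  # mean number of generated records per woman per outcome (Poisson);
  # calibrated so the median systolic-BP count is 6
  base_counts: {sbp: 6.0, dbp: 6.0, bmi: 3.0, total_chol: 0.25, hdl_chol: 0.25, glucose: 0.62}
  # observation-rate multipliers by derived APO-count group (measurement
  # availability is higher for women with APOs)
  group_multipliers: {"0": 1.0, "1": 1.15, "2": 1.3, "3+": 1.45}
  fasting_prob: 0.5       # glucose records only

truth:
  # anchor values of the true group-mean curves; keys are years relative
  # to first pregnancy start.  Curves are quadratic per pre/post segment,
  # value- and slope-continuous at t=0, and exact at every anchor.
  anchors:
    sbp:
      "0":  {-10: 112.9, 0: 116.53, 10: 119.5, 15: 122.80}
      "1":  {-10: 115.1, 0: 118.46, 10: 121.2, 15: 124.25}
      "2":  {-10: 116.8, 0: 120.93, 10: 124.3, 15: 128.05}
      "3+": {-10: 119.6, 0: 123.73, 10: 127.1, 15: 130.85}
    dbp:
      "0":  {-10: 68.0, 0: 70.2, 10: 72.0, 15: 74.0}
      "1":  {-10: 69.2, 0: 71.4, 10: 73.2, 15: 75.2}
      "2":  {-10: 70.4, 0: 72.6, 10: 74.4, 15: 76.4}
      "3+": {-10: 72.0, 0: 74.2, 10: 76.0, 15: 78.0}
    bmi:
      "0":  {-10: 23.0, 0: 24.43, 10: 25.6, 15: 26.9}
      "1":  {-10: 23.6, 0: 25.03, 10: 26.2, 15: 27.5}
      "2":  {-10: 24.3, 0: 25.73, 10: 26.9, 15: 28.2}
      "3+": {-10: 25.2, 0: 26.63, 10: 27.8, 15: 29.1}
    total_chol:
      "0":  {-10: 4.50, 0: 4.72, 10: 4.90, 15: 5.10}
      "1":  {-10: 4.58, 0: 4.80, 10: 4.98, 15: 5.18}
      "2":  {-10: 4.66, 0: 4.88, 10: 5.06, 15: 5.26}
      "3+": {-10: 4.75, 0: 4.97, 10: 5.15, 15: 5.35}
    hdl_chol:
      "0":  {-10: 1.55, 0: 1.51, 10: 1.48, 15: 1.45}
      "1":  {-10: 1.52, 0: 1.48, 10: 1.45, 15: 1.42}
      "2":  {-10: 1.49, 0: 1.45, 10: 1.42, 15: 1.39}
      "3+": {-10: 1.45, 0: 1.41, 10: 1.38, 15: 1.35}
    glucose:
      "0":  {-10: 4.70, 0: 4.84, 10: 4.95, 15: 5.08}
      "1":  {-10: 4.78, 0: 4.92, 10: 5.03, 15: 5.16}
      "2":  {-10: 4.88, 0: 5.02, 10: 5.13, 15: 5.26}
      "3+": {-10: 5.05, 0: 5.19, 10: 5.30, 15: 5.43}
  # between-woman intercept SD and residual SD per outcome.  Deliberately
  # small: the default cohort is a verification cohort in which anchor
  # recovery isolates systematic error; scale both up with noise_scale to
  # explore realistic-noise regimes.
  noise:
    sbp:        {intercept_sd: 1.2,  residual_sd: 2.5}
    dbp:        {intercept_sd: 1.0,  residual_sd: 2.0}
    bmi:        {intercept_sd: 0.8,  residual_sd: 0.8}
    total_chol: {intercept_sd: 0.15, residual_sd: 0.25}
    hdl_chol:   {intercept_sd: 0.06, residual_sd: 0.08}
    glucose:    {intercept_sd: 0.12, residual_sd: 0.25}
  noise_scale: 1.0
  # mean-centred covariate effects (units of the outcome); townsend is a
  # linear per-quintile trend
  covariate_effects:
    sbp:        {smoking_ever: 0.8,  townsend_quintile: 0.3}
    dbp:        {smoking_ever: 0.5,  townsend_quintile: 0.2}
    bmi:        {smoking_ever: 0.3,  townsend_quintile: 0.15}
    total_chol: {smoking_ever: 0.10, townsend_quintile: 0.02}
    hdl_chol:   {smoking_ever: -0.05, townsend_quintile: -0.01}
    glucose:    {smoking_ever: 0.05, townsend_quintile: 0.02}
  fasting_effect: -0.5   # glucose, fasting vs non-fasting (mean-centred)
  # plausibility bounds applied by rejection re-draw of the residual
  bounds:
    sbp: [60.0, 250.0]
    dbp: [30.0, 150.0]
    bmi: [12.0, 60.0]
    total_chol: [1.0, 15.0]
    hdl_chol: [0.3, 5.0]
    glucose: [2.0, 30.0]
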