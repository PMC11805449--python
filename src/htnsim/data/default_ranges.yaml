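# Default sampling configuration for setting-scenarios.
#
# Each leaf is one of:
#   {uniform: [low, high]}     continuous, sampled uniformly
#   {loguniform: [low, high]}  continuous, uniform on log scale
#   {choices: [v1, v2, ...]}   categorical, uniform over the listed set
#   {const: value}             fixed (still configurable here, never hard-coded)
#
# The ranges are stand-ins calibrated so that standard-of-care output for
# 2013-2016 lands inside the published care-cascade calibration envelopes
# (see htnsim.scenarios.CALIBRATION_ENVELOPES and docs/methods.md).

schema_version: {const: "1"}

sbp:
  # Population mean pre-treatment SBP profile: anchor values (mmHg) at decade
  # midpoints, shared by both sexes before the sex offset is applied.
  anchors:
    const: {20: 124.0, 30: 128.5, 40: 131.6, 50: 136.0, 60: 139.3, 70: 142.6, 80: 144.5}
  level_shift: {uniform: [-3.0, 3.0]}     # mmHg, setting-level shift of the whole profile
  tilt_per_year: {uniform: [-0.08, 0.08]} # mmHg/yr, extra tilt of the profile about age 50
  sex_offset: {const: 2.0}                # mmHg, men +offset, women -offset
  sd_between: {uniform: [11.0, 13.0]}     # mmHg, between-person SD at cohort entry
  rw_sd: {uniform: [0.25, 0.45]}          # mmHg, within-person random-walk SD per quarter
  secular_trend: {choices: [0.0, 0.5, 1.0]}  # mmHg per decade after 2015
  floor: {const: 90.0}                    # mmHg, physiologic floor under treatment

measurement_noise_sd: {uniform: [6.0, 10.0]}  # mmHg, SD of a single BP measurement

care:
  # Per-quarter probability of a blood-pressure-measuring clinic contact for
  # the 45-54 reference band; other bands scale by the age multipliers.
  presentation_base: {uniform: [0.013, 0.026]}
  presentation_age_mult:
    const: {"15-24": 0.5, "25-34": 0.7, "35-44": 0.85, "45-54": 1.0,
            "55-64": 1.1, "65-74": 1.3, "75+": 1.3}
  # Per-quarter probability that a person on ART attends their HIV clinic;
  # under integrated chronic-care policies BP is measured at these visits.
  hiv_clinic_presentation_prob: {uniform: [0.8, 0.95]}
  chw_coverage: {uniform: [0.55, 0.85]}       # annual reach of a CHW screening round
  linkage_prob: {uniform: [0.6, 0.9]}         # screen-positive -> confirmatory clinic visit
  treat_initiation_prob: {uniform: [0.2, 0.5]}
  adherence_prob: {uniform: [0.7, 0.85]}      # per-quarter adherence while dispensed
  never_engage_frac: {uniform: [0.10, 0.25]}  # permanently non-engaging fraction
  per_drug_sbp_reduction: {uniform: [5.0, 9.0]}  # mmHg per drug while adherent
  retention:
    soc_disengage: {uniform: [0.08, 0.16]}  # per-quarter, standard of care
    soc_reengage: {uniform: [0.03, 0.07]}
    ccc_disengage: {uniform: [0.02, 0.06]}  # per-quarter, chronic-care model (CCC/CHW)
    ccc_reengage: {uniform: [0.08, 0.16]}

hiv:
  prevalence_15_49: {loguniform: [0.03, 0.40]}
  art_coverage: {uniform: [0.6, 0.85]}
  cvd_rr: {uniform: [1.3, 2.2]}              # CVD hazard multiplier for HIV-positive
  excess_mortality_on_art: {uniform: [0.002, 0.006]}    # per-quarter
  excess_mortality_untreated: {uniform: [0.015, 0.04]}  # per-quarter
  incidence_scalar: {const: 0.012}  # per-quarter infection prob = scalar * prevalence

cvd:
  base_rate_scalar_ihd: {uniform: [0.6, 1.5]}
  base_rate_scalar_stroke: {uniform: [0.6, 1.5]}
  # Baseline per-quarter event probability at age 60 / SBP 115 / sex factor 1.
  base_quarterly_ihd: {const: 0.0011}
  base_quarterly_stroke: {const: 0.00090}
  age_log_slope: {const: 0.095}  # per year of age, Gompertz slope of baseline hazard
  sex_mult:
    const: {IHD: {M: 1.3, F: 0.7}, stroke: {M: 1.0, F: 1.0}}
  rr10_age50: {const: 0.80}  # relative risk per 10 mmHg lower SBP at age 50
  rr10_age80: {const: 0.90}  # attenuated value at age 80 (linear in between)
  severity_mild_ihd: {uniform: [0.30, 0.40]}
  severity_severe_ihd: {uniform: [0.20, 0.30]}
  severity_mild_stroke: {uniform: [0.10, 0.20]}
  severity_severe_stroke: {uniform: [0.35, 0.45]}
  acute_mortality:
    const:
      IHD: {mild: 0.0, moderate: 0.15, severe: 0.40}
      stroke: {mild: 0.0, moderate: 0.20, severe: 0.45}
  effective_care_mortality_reduction: {const: 0.30}
  care_seek_prob: {choices: [0.2, 0.4, 0.8]}
  care_effective_prob: {choices: [0.125, 0.25, 0.5]}
  chronic_mortality:
    const: {mild: 0.0008, moderate: 0.0030, severe: 0.0070}  # per-quarter, survivors
  prior_cvd_rr: {const: 2.5}
  disability_weights:
    const:
      IHD: {mild: 0.033, moderate: 0.08, severe: 0.18}
      stroke: {mild: 0.019, moderate: 0.32, severe: 0.55}

econ:
  ineffective_cost_fraction: {choices: [0.25, 0.5, 1.0]}
  integrated_visit_mode: {choices: [zero_added_cost, half_standalone_cost]}
  unit_costs:
    const:
      chw_screen_per_person: 3.0
      visit_uncontrolled: 10.0
      visit_controlled: 5.0
      drug_quarter_line12: 1.5
      drug_quarter_line3: 3.0
      clinic_training_annual_per_10k: 500.0
      acute_cvd_effective:
        IHD: {mild: 0.0, moderate: 600.0, severe: 1200.0}
        stroke: {mild: 0.0, moderate: 800.0, severe: 1500.0}
  cost_multipliers:
    const: {screening: 1.0, clinic: 1.0, drug: 1.0, cvd_care: 1.0}

demography:
  gompertz_a_f: {const: 0.0028}   # per-year background mortality hazard at age 50, women
  gompertz_a_m: {const: 0.0038}   # per-year background mortality hazard at age 50, men
  gompertz_b: {const: 0.09}       # per year of age
  init_age_decay: {const: 0.045}  # exponential decay of the initial adult age pyramid
  pop_growth_annual: {const: 0.01}  # net growth of the adult population beyond replacement
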