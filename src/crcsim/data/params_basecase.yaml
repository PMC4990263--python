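# Base-case model parameters (published values; costs in yuan).
# frailty_mean and other_cause_mortality are the two calibrated quantities:
# the source gives only the frailty coefficient of variation (1.7) and is
# silent on background mortality.  See docs/methods.md for the calibration.
natural_history:
  baseline_incidence:          # annual no-adenoma -> diminutive-adenoma rate
    - [20, 39, 0.003]
    - [40, 49, 0.007]
    - [50, 54, 0.019]
    - [55, 59, 0.022]
    - [60, 64, 0.024]
    - [65, 69, 0.028]
    - [70, 74, 0.033]
    - [75, 90, 0.035]
  frailty_mean: 0.0225         # calibrated (see docs/methods.md)
  frailty_sd_factor: 1.7       # published SD of incidence factor
  frailty_mode: additive
  diminutive_to_small: 0.03
  small_to_large: 0.05
  small_to_diminutive: 0.195
  large_to_small: 0.05
  villosity: [0.003, 0.015, 0.07]    # tubular -> villous, by size D/S/L
  dysplasia: [0.004, 0.006, 0.007]   # low -> high grade, by size D/S/L
  adv_adenoma_to_pec: 0.016
  pec_to_cac: 0.3
  pec_to_death: 0.18
  cec_to_resection: 0.96
  cec_to_death: 0.04
  resection_to_pec: 0.1137
  resection_to_cac: 0.1439
  recurrence_mode: once        # recurrence fate fixed at curative resection
  cac_to_death: 0.13
  advanced_definition: any     # large OR villous OR high-grade
  other_cause_mortality:       # calibrated residual non-CRC mortality
    - [20, 24, 0.00008]
    - [25, 29, 0.00009]
    - [30, 34, 0.00011]
    - [35, 39, 0.00015]
    - [40, 44, 0.0002]
    - [45, 49, 0.0003]
    - [50, 54, 0.0005]
    - [55, 59, 0.0008]
    - [60, 64, 0.0012]
    - [65, 69, 0.0019]
    - [70, 74, 0.0032]
    - [75, 79, 0.0054]
    - [80, 84, 0.009]
    - [85, 90, 0.015]

sensitivities:
  colonoscopy: [0.74, 0.87, 0.979]   # diminutive, small, large adenoma
  colonoscopy_cancer: 0.99
  fit: [0.0014, 0.12, 0.29]
  fit_cancer: 0.79
  fit_specificity: 0.95        # literature-typical; not printed in the source

economics:
  c_fit: 9
  c_colonoscopy: 290
  c_pathology: 150
  c_colo_with_polypectomy: 500
  c_early_treatment: 4650
  c_advanced_treatment: 26750
  cost_mapping: listed         # 290 + 150 per exam + 500 per adenoma removed
  advanced_cost_mode: once     # treatment initiation charged at entry
  discount_rate: 0.03
  t_start: 45
  t_end: 90
  utilities:
    healthy: 1.0
    small_adenoma: 0.955
    advanced_adenoma: 0.8
    early_cancer: 0.6
    advanced_cancer: 0.25
    death: 0.0
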