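# The ten FIT-plus-colonoscopy strategies compared in the base case.
# t_fit: FIT interval (years). t_colo: surveillance colonoscopy interval by
# finding class of the previous colonoscopy; null = no further colonoscopy
# (and no further screening of any kind) — at most one colonoscopy per
# lifetime for persons whose findings are always in a null class.
strategies:
  - name: "1"
    t_fit: 2
    t_colo: {no_adenoma: 3, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "2"
    t_fit: 2
    t_colo: {no_adenoma: 10, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "3"
    t_fit: 2
    t_colo: {no_adenoma: null, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "4"
    t_fit: 2
    t_colo: {no_adenoma: 10, small_1_2: 10, small_3_10: 10, advanced: 10, early_cancer: 10}
  - name: "5"
    t_fit: 1
    t_colo: {no_adenoma: 3, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "6"
    t_fit: 1
    t_colo: {no_adenoma: 10, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "7"
    t_fit: 1
    t_colo: {no_adenoma: 10, small_1_2: 6, small_3_10: 4, advanced: 4, early_cancer: 2}
  - name: "8"
    t_fit: 1
    t_colo: {no_adenoma: null, small_1_2: 3, small_3_10: 3, advanced: 3, early_cancer: 3}
  - name: "9"
    t_fit: 1
    t_colo: {no_adenoma: 10, small_1_2: 10, small_3_10: 10, advanced: 10, early_cancer: 10}
  - name: "10"
    t_fit: 1
    t_colo: {no_adenoma: null, small_1_2: 6, small_3_10: 4, advanced: 4, early_cancer: 2}
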