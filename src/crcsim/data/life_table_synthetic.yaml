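# OPTIONAL age-banded other-cause mortality (annual death probability).
# SYNTHETIC: a smooth abridged approximation in the ballpark of an East-Asian
# national life table, NOT an official table. The base case runs WITHOUT
# background mortality (other_cause_mortality: null); load these bands into
# NaturalHistoryParams.other_cause_mortality to enable it.
other_cause_mortality:
  - [20, 24, 0.0008]
  - [25, 29, 0.0009]
  - [30, 34, 0.0011]
  - [35, 39, 0.0015]
  - [40, 44, 0.0020]
  - [45, 49, 0.0030]
  - [50, 54, 0.0050]
  - [55, 59, 0.0080]
  - [60, 64, 0.0120]
  - [65, 69, 0.0190]
  - [70, 74, 0.0320]
  - [75, 79, 0.0540]
  - [80, 84, 0.0900]
  - [85, 90, 0.1500]
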