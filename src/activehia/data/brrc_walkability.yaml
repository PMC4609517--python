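# Urban-corridor (BRRC-like) walkability fixture: raw component values plus the
# shared normalization statistics, chosen to yield walkability scores of -3.61
# before and 0.96 after plan build-out (change +4.57), and the calibrated
# linear score->behavior mapping (20.3 pp low->high and +17 min/week over the
# +4.57 score change).
normalization:
  means: [90.0, 5.0, 0.6, 0.75]
  sds: [25.0, 2.0, 0.25, 0.2]
before:
  intersection_density: 60.0
  residential_density: 4.3
  retail_FAR: 0.5370127190956004
  landuse_components: [0.7, 0.2, 0.05, 0.05]
after:
  intersection_density: 95.0
  residential_density: 4.9
  retail_FAR: 0.5359754095806153
  landuse_components: [0.4, 0.3, 0.2, 0.1]
mapping:
  low_to_high_per_unit: 0.044420131291028446
  minutes_per_unit: 3.785557986870897
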