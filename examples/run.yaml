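# Full pipeline run over previously generated (or real, harmonized) bundles.
bundles:
  - bundles/north-a
  - bundles/north-b
  - bundles/island
  - bundles/centre
recruitment_year: 2015
gap_days: 90
discharge_followup_days: 14
rounding: 1
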