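# Eight candidate combination regimens: rHuEPO 50 IU/kg IV thrice weekly
# for 16 weeks plus intermittent romiplostim 1 ug/kg SC.
defaults:
  epo_dose_per_kg: 50.0
  epo_pattern: TIW
  epo_route: IV
  romi_dose_per_kg: 1.0
  duration_weeks: 16
  body_weight: 70.0
regimens:
  1: {romi_interval_weeks: 1, romi_start_week: 1}
  2: {romi_interval_weeks: 2, romi_start_week: 1}
  3: {romi_interval_weeks: 2, romi_start_week: 2}
  4: {romi_interval_weeks: 3, romi_start_week: 1}
  5: {romi_interval_weeks: 3, romi_start_week: 2}
  6: {romi_interval_weeks: 2, romi_start_week: 3}
  7: {romi_interval_weeks: 4, romi_start_week: 1}
  8: {romi_interval_weeks: 4, romi_start_week: 2}
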