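# Example end-to-end configuration.  Sections map onto PipelineConfig;
# unset keys keep their documented defaults.
cohort:
  n_participants: 150
  protocol_days: 182
  seed: 20
  archetype_mix: [0.28, 0.429, 0.291]
  age_effect_per_decade: 1.14
  monthly_schedule_effect: 1.24
  npc_nonwear_rate: 0.8
  withdrawal_hazard_low: 0.002
detection:
  window_minutes: 30
  movement_threshold: 0.013
  temperature_threshold_c: 25.0
regression:
  zero_handling: exclude
valid_threshold_hours: 22.0
period_edges: [60, 120]
emit_epoch_days: 3
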