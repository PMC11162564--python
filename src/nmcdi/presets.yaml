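# Versioned named scenario presets for the synthetic-session generator.
# Values not listed fall back to the ScenarioSpec defaults (clean study
# conditions: 4 PEEP levels +2 cmH2O/step including the 9 cmH2O reference,
# 3 occlusions per level, NMC decline 4.9 pp per cmH2O).

clean: {}

low_snr:
  target_snr_pct: 120.0
  defect: low_snr

high_aub:
  target_snr_pct: 250.0
  defect: high_aub

cardiac_locked:
  defect: cardiac_locked
  burst_width_s: 0.10

non_bell:
  defect: non_bell
  burst_shape: double_spike

abrupt_pocc:
  defect: abrupt_pocc
  pocc_release: abrupt

mixed:
  defect: mixed
  occlusions_per_level: 6
  duration_per_level_s: 60.0
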