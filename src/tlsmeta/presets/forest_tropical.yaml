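# Tropical forest variant: dense leafy understory, low canopy gaps, strong
# absorption of pulse energy (low reflectance). Illustrative, not calibrated.
scene: forest
config:
  canopy_base_height: 10.0
  canopy_top_height: 22.0
  canopy_gap_prob: 0.10
  understory_density: 0.12
  trunk_count: 16
  trunk_radius: 0.35
  stand_radius: 30.0
  second_return_prob: 0.35
  reflectance_mean: 0.25
  reflectance_sd: 0.07
  range_noise_sd_m: 0.05
  max_range_clip: 40.0
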