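# Inland tropical rainforest variant: tall canopy, longer sight-lines
# between large trunks. Illustrative, not calibrated to any site.
scene: forest
config:
  canopy_base_height: 14.0
  canopy_top_height: 26.0
  canopy_gap_prob: 0.08
  understory_density: 0.08
  trunk_count: 14
  trunk_radius: 0.40
  stand_radius: 30.0
  second_return_prob: 0.30
  reflectance_mean: 0.24
  reflectance_sd: 0.07
  range_noise_sd_m: 0.05
  max_range_clip: 40.0
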