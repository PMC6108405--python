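# Coastal tropical rainforest variant: shorter canopy, denser low growth,
# shorter sight-lines. Illustrative, not calibrated to any site.
scene: forest
config:
  canopy_base_height: 8.0
  canopy_top_height: 16.0
  canopy_gap_prob: 0.12
  understory_density: 0.15
  trunk_count: 18
  trunk_radius: 0.30
  stand_radius: 25.0
  second_return_prob: 0.32
  reflectance_mean: 0.27
  reflectance_sd: 0.07
  range_noise_sd_m: 0.05
  max_range_clip: 40.0
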